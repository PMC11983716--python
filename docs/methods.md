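# Methods

## Model

`mslambda` implements the alchemical machinery of multisite λ-dynamics on a
*reduced* Hamiltonian. The Cartesian force-field terms that an all-atom
engine would evaluate — environment self-interaction, substituent–environment
and substituent self-interactions, and substituent–substituent cross terms —
are collapsed to scalar effective energies:

    V(λ) = E_env + Σ_si λ_si·h_si + Σ_{s<t} Σ_ij λ_si·λ_tj·J_{si,tj} + V_bias(λ)

with `h` in kcal/mol per (site, substituent) and `J` a symmetric inter-site
coupling matrix whose intra-site blocks are identically zero (two
substituents of one site are never simultaneously physical). This preserves
the two structural features that make multisite λ-dynamics what it is — the
linear λ-scaling of environment terms and the bilinear inter-site terms —
while making brute-force and quadrature oracles exact. Nothing here claims
atomistic realism: there are no Cartesian coordinates, no solvent, no
soft-core potentials, and absolute ΔG magnitudes of solvated complexes
(hundreds of kcal/mol) are out of reach by construction.

### Implicit constraints

The constraints Σ_i λ_si = 1, λ_si ∈ [0, 1] are enforced implicitly through
a per-site exponential normalization (softmax) of unconstrained coordinates,

    λ_si = exp(α θ_si) / Σ_j exp(α θ_sj),

with steepness α = 5.5 by default, the standard choice in the λ-dynamics
literature. The transform is smooth, exactly constraint-preserving
(evaluated with per-site max subtraction; λ may underflow to exactly 0 for
very negative θ, which is harmless), and invariant to a per-site constant
shift of θ — a gauge direction with no physical content. The exact
functional form used by production λ-dynamics engines is not printed in the
sources this package follows; the softmax is a documented substitute with
the same contract, not a claim about those codes.

### θ confinement

V(λ(θ)) is constant on the plateaus where the softmax has saturated, so the
Boltzmann measure over unconstrained θ would not be normalizable. A weak
harmonic restraint ½·k_θ·|θ|² (default k_θ = 0.3 kcal/mol per θ² unit)
confines θ. Three consequences:

* the gauge direction becomes a bounded, independent Gaussian whose factor
  cancels exactly from every population ratio;
* the sampled ensemble is well-defined, and the quadrature oracle integrates
  the *identical* restrained potential, so sampler and oracle always refer
  to the same ensemble — the restraint can never silently bias a comparison;
* the restraint is symmetric between substituents, so its (small) effect on
  endstate bin masses largely cancels in free-energy *differences*.

## Sampler

BAOAB-splitting Langevin dynamics on θ at fixed temperature (298 K;
k_B = 0.0019872041 kcal/mol/K everywhere). With zero friction the O-step is
the identity and the integrator reduces to velocity Verlet. All model units:
θ mass 1, timestep 0.01, friction 2 — chosen so a symmetric two-substituent
site yields a usable transition rate (≈ 0.5 endstate transitions per 1000
steps; the femtosecond/nanosecond timescales of molecular engines do not
transfer to the reduced model). Initial θ is standard normal, initial
velocities Maxwell–Boltzmann, both from the seeded generator; noise is drawn
outside the compiled kernel in fixed-size chunks, so trajectories are
bit-reproducible for a given seed regardless of compilation. Replica and
iteration seeds derive from the master seed through a splitmix-style mixer,
avoiding correlated streams.

Boltzmann fidelity is verified two ways: equipartition of harmonic θ
(variance = k_BT/k within 3 SE, with the SE corrected by the measured
integrated autocorrelation time) and a Kolmogorov–Smirnov test of the θ-gap
marginal against dense quadrature of the exact density, pre-registered at
level 0.01 with a subsampling stride of 40 frames (2000 steps), beyond the
measured well correlation time.

## Adaptive landscape flattening

The bias family is linear (−b_si·λ_si), intra-site quadratic
(ψ_s,ij·λ_si·λ_sj, i ≠ j) and inter-site quadratic coupling
(−Ψ_si,tj·λ_si·λ_tj on Watson–Crick paired sites, with reference rows and
columns pinned to zero). The loop alternates short runs with damped
parameter updates over a phase schedule (many short iterations, a few medium
refinements, then production runs with further refinement after each run —
the default schedule mirrors that structure at 10×10³ / 10×10⁴ /
5×10⁴–10⁶-step scale, and `FlatteningSchedule.quick()` keeps the same phase
structure at desk scale). Because each iteration is reweighted only against
its own bias, the multi-ensemble machinery of WHAM reduces to
single-ensemble histogram reweighting.

Design choices that mattered:

* **Geometric measure reference.** Under the softmax transform the λ
  marginal of even a *flat* energy landscape is strongly non-uniform (the
  mid-λ region maps to a narrow θ slice). The sampled histogram is therefore
  read against the analytically known bin measure of the transform (exact
  Gaussian masses between logit-transformed bin edges), and the ALF update
  flattens the resulting *energy* landscape, not the raw histogram.
  Flattening the raw histogram would dig a spurious energetic well at mid-λ
  and suppress endstate populations.
* **Region-coarse estimates.** Endpoint and barrier residuals are estimated
  from three coarse regions (outer λ quarters and interior) by aggregate
  frame mass, not per-bin log-counts: sparsely occupied bins give
  systematically low −kT·ln(p) estimates (occupancy conditioning), which
  destabilized per-bin updates.
* **Damped residual updates with production decay.** Linear coefficients are
  incremented by damping × (well free-energy difference of the sampled
  landscape); the flattened landscape is the fixed point, so the converged
  coefficients equal the endpoint free-energy differences. The damping
  (default 0.8, increments clipped at ±5 kcal/mol) is halved at each
  successive production phase so the converged coefficients stop
  random-walking with per-run estimation noise. A well never visited is
  pushed toward by k_BT·ln(n) per update.
* **Warm starts.** Each flattening iteration continues from the previous
  iteration's final θ state; cold random starts contaminated short
  iterations with their equilibration transient.
* Profiles use 25 bins over [0, 1]; uncertainties are moving-block
  bootstrap (50 resamples, block length = frames/20, minimum 1). Empty bins
  are flagged, never imputed.

## Perturbation schemes

`one_lambda_per_pair` drives each base-pair transformation with a single λ
(substituents are whole Watson–Crick pairs; mispairing is impossible).
`two_lambda` gives each strand's base its own λ on a pair of linked sites;
vertex states may be mispaired, and the toy Hamiltonians charge such states
a mispair penalty (default 2 kcal/mol) per mispaired position.
`coupled_two_lambda` adds a quadratic inter-site coupling Ψ between the
paired sites' λ variables. With the reference rows of Ψ pinned to zero, the
only gauge available to express strand *decoupling* is a penalty −Ψ₀ on the
matched non-reference pair: up to per-site linear terms (which the
flattening bias absorbs), destabilizing the concerted double mutation by Ψ₀
is equivalent to stabilizing the mispaired intermediates, cancelling the
pairwise cooperativity between the strands so single-strand flips are no
longer blocked. Ψ₀ defaults to the toy mispair penalty (2 kcal/mol), which
removes about half the mispair barrier after flattening; it is a free
parameter of the scheme. The observable consequence — reproduced by the
test suite — is that the coupled scheme spreads a larger fraction of its
transitions over mismatched states, at the cost of undersampling the
matched states of interest, while the single-λ scheme concentrates all its
transitions on physical sequences.

Sequences are reported in the primary-strand convention; mispaired vertices
are labeled `primary|implied-complement` so every vertex is distinguishable.

## Estimators

Frames are binned to endstates at λc = 0.99 (a frame belongs to sequence m
iff λ ≥ λc at every site; raising λc never assigns more frames). The
population estimator subtracts the applied linear-bias energy at each
vertex, which makes it valid on imperfectly flattened landscapes; a flag
disables the correction to mimic the perfectly-flattened assumption. The
same correction (and the same λc bins) are used by the quadrature oracle,
so estimator and oracle always measure the same quantity. A transition is
the entry into an endstate bin different from the last-visited endstate;
unassigned gaps are transparent, the first visit is not a transition, and
replica boundaries reset the visit history. Sequences never observed are
reported as missing, not infinite. ΔΔG legs combine by subtraction with
standard errors in quadrature; unavailable legs propagate unavailability.
Rates are reported per unit model time and carry no nanosecond claim.

## Toy systems and oracles

Sequence-level well-depth tables (bound and unbound) are realized exactly on
1–2 variant positions: `h` carries the single-position contributions, `J`
the two-position interaction, and — in the 2λ schemes — the mispair
penalty. Every properly paired vertex energy equals its table entry
exactly. The `wbox` preset places the native sequence at 0 and the mutants
at 2 / 4 / 5.7 kcal/mol in the bound ensemble (the per-mutant scale of the
W-box motif) with a sequence-indifferent unbound ensemble; the standard
two-pair toy is fully symmetric with a 2 kcal/mol mispair penalty and is
used for the scheme comparison.

The quadrature oracle integrates exp(−V/k_BT) over the gauge-fixed θ
subspace (one gap coordinate per two-substituent site, at most 4
dimensions) with Simpson's rule on product grids aligned exactly to each
sequence's λc bin, so there are no indicator discontinuities; doubling the
grid changes ΔG by < 10⁻⁴ kcal/mol at defaults. It refuses sites with more
than two substituents and more than four sites — it is deliberately
small-scale.

## What the toys do and do not show

Passing tests demonstrate that the sampling, flattening, binning and
cycle-assembly machinery is internally exact and statistically calibrated
against known answers. They do not probe force-field realism, solvent,
conformational relaxation of the complex, flanking-sequence effects, or the
absolute free-energy scale of a solvated protein–DNA system; the reduced
model has no analogue of those. Problem sizes are the package's defaults:
flattening at 8×5000 + 4×15000 steps plus production refinements,
production runs of 10⁵ steps × 5 replicas, 20-system batteries for the
statistical acceptance properties.

## Known limitations

* The geometric measure reference is exact for two-substituent sites and an
  approximation (coordinate vs aggregate rest) for larger sites.
* The per-coordinate bias subtraction in profiles attributes intra-site
  quadratic terms through the two-substituent marginal assumption
  λ_sj = (1 − λ_si)/(N_s − 1); inter-site Ψ contributions are left in the
  sampled landscape (the updates operate on the sampled landscape, so
  nothing is lost for flattening).
* Depth tables with three or more variant positions would need three-body
  terms the reduced Hamiltonian deliberately lacks; construction refuses
  them.
* Block bootstrap mildly underestimates uncertainties for strongly
  correlated trajectories; the calibration test brackets the nominal 1-SE
  coverage at 55–80%.
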