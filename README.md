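# mslambda

Desk-scale **multisite λ-dynamics** for protein–DNA binding specificity:
alchemical free-energy machinery — composite λ potential with implicit
constraints, Langevin sampling of the alchemical coordinates, adaptive
landscape flattening (ALF), base-pair perturbation schemes, endstate
population estimators with block-bootstrap uncertainties, and
thermodynamic-cycle ΔΔG assembly — exercised on reduced model Hamiltonians
whose exact answers are available by quadrature.

## The problem

Transcription factors recognize specific DNA motifs; the WRKY family binds
the W-box element `GGTCAA`. The observable of interest is the change in
binding free energy when the motif is mutated,

    ΔΔG_b(S1 → S2) = ΔG_mut(bound) − ΔG_mut(unbound),

obtained from a thermodynamic cycle in which the sequence is *alchemically*
mutated in the protein-bound and free-DNA ensembles. In multisite
λ-dynamics each mutable site *s* carries one coupling variable λ_si per
substituent *i*; the λ's are dynamical coordinates, and the potential is

    V(λ) = E_env + Σ_si λ_si·h_si + Σ_{s<t} Σ_ij λ_si·λ_tj·J_{si,tj} + V_bias(λ)

subject to Σ_i λ_si = 1, λ_si ∈ [0, 1]. The constraints are maintained
implicitly: unconstrained coordinates θ are propagated by BAOAB Langevin
dynamics and mapped through a per-site softmax λ_si ∝ exp(α·θ_si). A frame
is assigned to sequence *m* when λ ≥ λc (default 0.99) for every substituent
*m* prescribes, and

    ΔG_m = −k_B T · ln(P_m / P_ref) − (B_m − B_ref)

where P are assigned-frame fractions and B the applied linear-bias energies.
Because free energies converge only through repeated endstate transitions,
ALF iteratively tunes V_bias (linear, intra-site quadratic, and — for the
coupled two-λ scheme — inter-site quadratic Ψ terms) until the landscape is
flat and all endstates are visited.

This package replaces the all-atom force field with scalar effective
energies (per-substituent well depths `h`, inter-site couplings `J`), which
keeps the entire alchemical structure intact while making **exact oracles**
feasible: every estimate the sampler produces can be checked against dense
numerical quadrature of exp(−V/k_BT). Three DNA perturbation schemes are
implemented: one λ per base pair (`1l`), one λ per base (`2l`, paired sites
with mispair penalties), and `coupled2l` (2λ plus a tuned inter-site Ψ
coupling that decouples the two strands' transitions).

## Worked example

```bash
mslambda toy --preset wbox --scheme 1l --seed 1 --out config.yaml
mslambda flatten --config config.yaml --out run/bias
mslambda produce --config config.yaml --bias-dir run/bias --out run/traj
mslambda analyze --config config.yaml --bias-dir run/bias \
                 --traj-dir run/traj --out run/results
```

The `wbox` preset emulates the W-box → `GATAAA` study: bound-ensemble well
depths of 0 / 2 / 4 / 5.7 kcal/mol for `GGTCAA` / `GGTAAA` / `GATCAA` /
`GATAAA` and a sequence-indifferent unbound ensemble. A single mutation
study yields all intermediate mutants at once; the analysis prints a ranked
table (this output is from the pipeline above at production scale,
5 replicas × 10⁵ steps per ensemble):

```
sequence      ddg       se  n_frames_bound  n_frames_unbound  transitions
  GGTCAA 0.000000 0.000000             956               858           94
  GGTAAA 1.928587 0.122955            1505              1160          142
  GATCAA 3.933243 0.150597             700               948           98
  GATAAA 5.614649 0.128703            1685              1291          146
```

`ddg` is ΔΔG_b in kcal/mol relative to the native W-box (positive =
weakened binding), `se` its block-bootstrap standard error, and
`transitions` the number of endstate transitions observed in the bound
production runs — the convergence currency of λ-dynamics. The recovered
ΔΔG values match the constructed well depths within their uncertainties,
and the ranking of the mutants is exact.

The same machinery is available as a library:

```python
from mslambda import (ToySpec, make_toy_pair, alf_flatten, FlatteningSchedule,
                      SamplerSettings, quadrature_dg)

system = make_toy_pair(ToySpec.wbox())
bias, log = alf_flatten(system.topology, system.bound,
                        FlatteningSchedule.quick(), SamplerSettings(seed=1))
print(quadrature_dg(system.bound, system.topology, bias=bias))  # exact ΔG
```

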