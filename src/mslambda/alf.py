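"""Bias potentials and adaptive landscape flattening (ALF).

Free energies from λ-dynamics converge only through repeated endstate
transitions, so a bias V_bias(λ) is tuned to flatten the alchemical landscape.
The family implemented here is the minimal one sufficient for the reduced
Hamiltonians:

    V_bias(λ) = − Σ_si b_si λ_si                      (linear, per coordinate)
              + Σ_s Σ_{i≠j} ψ_{s,ij} λ_si λ_sj        (intra-site quadratic)
              − Σ_{paired s<t} Σ_ij Ψ_{si,tj} λ_si λ_tj   (inter-site coupling)

Sign conventions: a positive linear coefficient b_si *lowers* the energy of
substituent i at site s; a positive inter-site Ψ entry is *attractive* for the
(si, tj) combination.  Ψ rows and columns belonging to the reference
substituent (index 0) are identically zero.

The ALF loop alternates short trajectories with bias updates.  Each iteration
histograms the per-coordinate λ marginals of its own run, so the multi-state
reweighting of a full WHAM collapses to single-ensemble histogram reweighting.
Updates are damped residuals: the *sampled* (still-biased) landscape is
reconstructed and its endpoint imbalance and mid-λ barrier are pushed toward
zero, which has the flattened landscape as its unique fixed point and leaves
the converged linear coefficients equal to the endpoint free-energy
differences.  Per-bin uncertainties come from a moving-block bootstrap over
trajectory blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alchemical_core import (
    KB,
    AlchemicalTopology,
    LambdaState,
    ModelHamiltonian,
    ValidationError,
)
from .sampler import LambdaTrajectory, SamplerSettings, derive_seed, run_trajectory

__all__ = [
    "BiasParameters",
    "FlatteningPhase",
    "FlatteningSchedule",
    "FreeEnergyProfile",
    "FlatteningLogEntry",
    "bias_energy",
    "bias_gradient_lambda",
    "estimate_profile",
    "update_bias",
    "alf_flatten",
]


@dataclass
class BiasParameters:
    """All tunable bias coefficients over a topology (kcal/mol).

    ``linear[k]`` enters as −b_k λ_k; ``intra_quad`` is symmetric with zero
    diagonal and nonzero only within site blocks; ``inter_coupling`` holds the
    Ψ tensor (stored symmetrically, Ψ[si, tj] = Ψ[tj, si]), nonzero only on
    Watson–Crick paired site blocks and with zero reference rows/columns.
    """

    topology: AlchemicalTopology
    linear: np.ndarray | None = None
    intra_quad: np.ndarray | None = None
    inter_coupling: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.topology.n_coords
        self.linear = (
            np.zeros(n) if self.linear is None else np.asarray(self.linear, float)
        )
        self.intra_quad = (
            np.zeros((n, n))
            if self.intra_quad is None
            else np.asarray(self.intra_quad, float)
        )
        self.inter_coupling = (
            np.zeros((n, n))
            if self.inter_coupling is None
            else np.asarray(self.inter_coupling, float)
        )
        if self.linear.shape != (n,):
            raise ValidationError("linear bias shape does not match topology")
        for name, m in (("intra_quad", self.intra_quad), ("inter_coupling", self.inter_coupling)):
            if m.shape != (n, n):
                raise ValidationError(f"{name} shape does not match topology")
            if not np.allclose(m, m.T, atol=1e-12):
                raise ValidationError(f"{name} must be symmetric")
        if np.any(np.diag(self.intra_quad) != 0.0):
            raise ValidationError("intra_quad diagonal must be zero")
        intra = self.topology.intra_site_mask()
        if np.any(self.intra_quad[~intra] != 0.0):
            raise ValidationError("intra_quad must be zero between different sites")
        paired = self.topology.paired_block_mask()
        if np.any(self.inter_coupling[~paired] != 0.0):
            raise ValidationError(
                "inter_coupling must be zero except between Watson-Crick paired sites"
            )
        for s in range(self.topology.n_sites):
            ref = self.topology.coord_index(s, 0)
            if np.any(self.inter_coupling[ref, :] != 0.0) or np.any(
                self.inter_coupling[:, ref] != 0.0
            ):
                raise ValidationError(
                    "inter_coupling rows/columns of reference substituents must be zero"
                )

    @classmethod
    def zeros(cls, topology: AlchemicalTopology) -> "BiasParameters":
        return cls(topology)

    def copy(self) -> "BiasParameters":
        return BiasParameters(
            self.topology,
            self.linear.copy(),
            self.intra_quad.copy(),
            self.inter_coupling.copy(),
        )

    def vertex_linear_energy(self, selection: Sequence[int]) -> float:
        """Linear-bias energy −Σ b at a vertex (used for bias correction)."""
        lam = self.topology.vertex_lambda(selection)
        return -float(self.linear @ lam)


def bias_energy(lam: LambdaState, bias: BiasParameters) -> float:
    """Evaluate V_bias(λ) in kcal/mol."""
    if lam.topology.n_coords != bias.topology.n_coords:
        raise ValidationError("lambda and bias dimensions are inconsistent")
    x = lam.lam
    return float(
        -bias.linear @ x
        + x @ bias.intra_quad @ x
        - 0.5 * x @ bias.inter_coupling @ x
    )


def bias_gradient_lambda(lam: np.ndarray, bias: BiasParameters) -> np.ndarray:
    """∂V_bias/∂λ for the quadratic-form representation."""
    return -bias.linear + 2.0 * bias.intra_quad @ lam - bias.inter_coupling @ lam


# ---------------------------------------------------------------------------
# free-energy profiles
# ---------------------------------------------------------------------------


@dataclass
class FreeEnergyProfile:
    """Per-coordinate binned free-energy profiles over λ in [0, 1].

    ``values`` is the unbiased estimate −kT ln p − V_bias,along(λ) with the
    minimum of each occupied coordinate profile shifted to zero; ``raw`` keeps
    the sampled (still-biased) landscape used by the ALF update; ``se`` holds
    block-bootstrap standard errors and ``empty`` flags bins that received no
    frames (never silently imputed).
    """

    topology: AlchemicalTopology
    edges: np.ndarray  # (bins+1,), covering [0, 1] exactly
    values: np.ndarray  # (n_coords, bins)
    raw: np.ndarray  # (n_coords, bins)
    se: np.ndarray  # (n_coords, bins)
    empty: np.ndarray  # (n_coords, bins) bool
    temperature: float
    counts: np.ndarray | None = None  # (n_coords, bins) raw frame counts
    degenerate: bool = False  # all frames of some coordinate in one bin
    #: geometric reference: −kT ln of the bin measure that the
    #: implicit-constraint transform alone (zero energy landscape, θ
    #: confinement only) would produce.  ``raw − measure`` is the sampled
    #: *energy* landscape along the coordinate, which is what the ALF update
    #: flattens; without this reference the λ histogram shows a purely
    #: entropic mid-λ barrier that no bias should try to cancel.
    measure: np.ndarray | None = None

    def energy_landscape(self) -> np.ndarray:
        if self.measure is None:
            return self.raw
        return self.raw - self.measure

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def region_free_energies(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sampled energy of the λ→0 well, mid-λ region, and λ→1 well.

        The profile is coarse-grained into three regions (outer quarters and
        interior) and each region's aggregate frame mass is compared with its
        analytic measure mass, F_r = −kT ln[(c_r/n)/μ_r].  Aggregation keeps
        the counts large, avoiding the low bias of per-bin log estimates in
        sparsely occupied bins.  NaN where a region received no frames.
        """
        if self.counts is None:
            raise ValidationError("region free energies need frame counts")
        kT = KB * self.temperature
        bins = self.counts.shape[1]
        q = max(1, bins // 4)
        if self.measure is not None:
            mu = np.exp(-(self.measure - self.measure.min(axis=1, keepdims=True)) / kT)
        else:
            mu = np.ones_like(self.counts, dtype=float)
        mu = mu / mu.sum(axis=1, keepdims=True)
        regions = [slice(0, q), slice(q, bins - q), slice(bins - q, bins)]
        n = self.counts.sum(axis=1)
        out = []
        for r in regions:
            c_r = self.counts[:, r].sum(axis=1)
            mu_r = mu[:, r].sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                f = -kT * np.log((c_r / np.maximum(n, 1)) / mu_r)
            f[c_r == 0] = np.nan
            out.append(f)
        return out[0], out[1], out[2]

    def endpoint_imbalance(self) -> np.ndarray:
        """Residual sampled free-energy difference G(λ→1) − G(λ→0) per coordinate.

        NaN where an endpoint well could not be estimated (no frames).
        """
        f_lo, _, f_hi = self.region_free_energies()
        return f_hi - f_lo


def _bias_along(
    bias: BiasParameters, coord: int, lam_vals: np.ndarray
) -> np.ndarray:
    """Applied bias energy attributed to one λ coordinate.

    The linear term is exact.  Intra-site quadratic terms are evaluated on the
    per-site marginal assumption λ_sj = (1 − λ_si)/(N_s − 1) for j ≠ i, which
    is exact for two-substituent sites.  Inter-site Ψ terms involve the other
    site's coordinates and are not attributable to a single marginal; they are
    left in the sampled landscape (the ALF update works on the sampled
    landscape, so no bias is lost).
    """
    topo = bias.topology
    s, i = topo.site_of_coord(coord)
    sl = topo.site_slice(s)
    ns = topo.sites[s].n
    other = (1.0 - lam_vals) / (ns - 1)
    e = -bias.linear[coord] * lam_vals
    psi = bias.intra_quad[sl, sl.start + i]  # column of site block
    cross = 2.0 * lam_vals * other * (psi.sum() - psi[i])
    # pairs among the remaining substituents, all at the shared marginal value
    block = bias.intra_quad[sl, :][:, sl]
    rest = block.sum() - 2.0 * psi.sum() + 2.0 * block[i, i]
    e = e + cross + rest * other**2
    return e


def _measure_profile(
    edges: np.ndarray,
    steepness: float,
    theta_restraint: float,
    kT: float,
) -> np.ndarray:
    """−kT ln of the per-bin measure of a two-substituent λ coordinate.

    Under the θ confinement the site's gap coordinate d = θ_si − θ_sj has the
    zero-energy marginal ∝ exp(−¼ k d²/kT) and λ = sigmoid(α d); each λ bin's
    measure is the exact Gaussian mass between the logit-transformed bin
    edges.  Sites with more substituents reuse this two-state geometry as an
    approximation (the coordinate against the aggregate of the others).
    """
    from scipy.special import ndtr

    if theta_restraint <= 0:
        return np.zeros(edges.shape[0] - 1)
    sigma = np.sqrt(2.0 * kT / theta_restraint)
    with np.errstate(divide="ignore"):
        d_edges = np.log(edges / (1.0 - edges)) / steepness
    p = np.diff(ndtr(d_edges / sigma))
    p = np.maximum(p, p[p > 0].min() * 1e-12)
    return -kT * np.log(p / p.sum())


def estimate_profile(
    trajs: Sequence[LambdaTrajectory] | LambdaTrajectory,
    bias: BiasParameters,
    bins: int = 25,
    n_boot: int = 50,
    rng: np.random.Generator | None = None,
    temperature: float = 298.0,
    steepness: float | None = None,
    theta_restraint: float | None = None,
) -> FreeEnergyProfile:
    """Histogram each λ_si marginal and convert to a free-energy profile.

    The trajectories must all have been generated under ``bias``.  Bootstrap
    resampling is over contiguous trajectory blocks (block length =
    frames/20, at least 1) to respect serial correlation.  ``steepness`` and
    ``theta_restraint`` default to the settings recorded on the first
    trajectory and parameterize the geometric measure reference (see
    :class:`FreeEnergyProfile`).
    """
    if isinstance(trajs, LambdaTrajectory):
        trajs = [trajs]
    if not trajs:
        raise ValidationError("estimate_profile needs at least one trajectory")
    rng = np.random.default_rng(0) if rng is None else rng
    topo = trajs[0].topology
    frames = np.concatenate([t.frames for t in trajs], axis=0)
    n_frames, n = frames.shape
    kT = KB * temperature
    edges = np.linspace(0.0, 1.0, bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def profile_raw(fr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        raw = np.full((n, bins), np.nan)
        counts = np.empty((n, bins))
        for k in range(n):
            c, _ = np.histogram(fr[:, k], bins=edges)
            counts[k] = c
            occ = c > 0
            raw[k, occ] = -kT * np.log(c[occ] / fr.shape[0])
        return raw, counts

    raw, counts = profile_raw(frames)
    empty = counts == 0
    degenerate = bool(np.any((counts > 0).sum(axis=1) == 1))

    values = np.full((n, bins), np.nan)
    for k in range(n):
        occ = ~empty[k]
        v = raw[k, occ] - _bias_along(bias, k, centers[occ])
        values[k, occ] = v - v.min()

    # moving-block bootstrap over the concatenated frames
    block = max(1, n_frames // 20)
    n_blocks = max(1, n_frames // block)
    boots = np.full((n_boot, n, bins), np.nan)
    for b in range(n_boot):
        starts = rng.integers(0, max(1, n_frames - block + 1), size=n_blocks)
        idx = (starts[:, None] + np.arange(block)[None, :]).ravel()[:n_frames]
        boots[b], _ = profile_raw(frames[idx])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        se = np.nanstd(boots, axis=0)
    se[empty] = np.nan
    se = np.where(np.isnan(se) & ~empty, 0.0, se)

    settings = trajs[0].settings
    if steepness is None:
        steepness = settings.steepness if settings is not None else 5.5
    if theta_restraint is None:
        theta_restraint = (
            settings.theta_restraint if settings is not None else 0.3
        )
    measure_row = _measure_profile(edges, steepness, theta_restraint, kT)
    measure = np.tile(measure_row, (n, 1))

    return FreeEnergyProfile(
        topology=topo,
        edges=edges,
        values=values,
        raw=raw,
        se=se,
        empty=empty,
        temperature=temperature,
        counts=counts,
        degenerate=degenerate,
        measure=measure,
    )


# ---------------------------------------------------------------------------
# ALF update
# ---------------------------------------------------------------------------


def update_bias(
    profile: FreeEnergyProfile,
    bias: BiasParameters,
    damping: float = 0.8,
    cap: float = 5.0,
) -> BiasParameters:
    """One damped ALF update; returns a new parameter set, input unmodified.

    Linear coefficients are incremented by damping × (well free-energy
    difference of the sampled energy landscape), which drives the residual
    endpoint imbalance to zero; intra-site quadratic couplings are
    incremented to cancel the residual mid-λ energy barrier (interior region
    relative to the wells).  The landscape is read as three coarse regions
    net of the geometric measure of the implicit-constraint transform
    (:meth:`FreeEnergyProfile.region_free_energies`), so a flat *energy*
    surface — not a flat λ histogram — is the fixed point.  Every increment
    is clipped to ±cap.  A coordinate whose wells are both unobservable is
    left unchanged (``no_update`` flag on the result).
    """
    if profile.topology.n_coords != bias.topology.n_coords:
        raise ValidationError("profile and bias topologies are inconsistent")
    if not 0.0 < damping <= 1.0:
        raise ValidationError("damping must be in (0, 1]")
    new = bias.copy()
    topo = bias.topology
    kT = KB * profile.temperature
    f_lo, f_mid, f_hi = profile.region_free_energies()
    n_per_coord = profile.counts.sum(axis=1)
    barriers = np.zeros(topo.n_coords)
    updated = np.zeros(topo.n_coords, dtype=bool)
    for k in range(topo.n_coords):
        lo, hi = f_lo[k], f_hi[k]
        if np.isnan(lo) and np.isnan(hi):
            continue
        if np.isnan(lo) or np.isnan(hi):
            # one well never visited: it lies at least kT ln(n) above the
            # occupied landscape, so push by that scale (a missing λ→1 well
            # means the substituent is disfavored there, raising its linear
            # coefficient)
            span = kT * np.log(max(float(n_per_coord[k]), 2.0))
            delta = span if np.isnan(hi) else -span
        else:
            delta = hi - lo
        new.linear[k] += float(np.clip(damping * delta, -cap, cap))
        updated[k] = True
        if not (np.isnan(lo) or np.isnan(hi) or np.isnan(f_mid[k])):
            # signed residual: negative once the mid region has been pushed
            # below the wells, so the flat energy landscape is a stable
            # fixed point
            barriers[k] = f_mid[k] - 0.5 * (lo + hi)
    for s in range(topo.n_sites):
        sl = topo.site_slice(s)
        for i in range(topo.sites[s].n):
            for j in range(i + 1, topo.sites[s].n):
                ki, kj = sl.start + i, sl.start + j
                if not (updated[ki] and updated[kj]):
                    continue
                bar = 0.5 * (barriers[ki] + barriers[kj])
                # a pair increment δψ shifts the mid-λ landscape by ~δψ/2
                dpsi = float(np.clip(-2.0 * damping * bar, -cap, cap))
                new.intra_quad[ki, kj] += dpsi
                new.intra_quad[kj, ki] += dpsi
    new.no_update = not bool(updated.any())  # type: ignore[attr-defined]
    return new


# ---------------------------------------------------------------------------
# flattening schedule and loop
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FlatteningPhase:
    n_iterations: int
    n_steps: int
    update: bool = True
    production: bool = False

    def __post_init__(self) -> None:
        if self.n_iterations < 1 or self.n_steps < 1:
            raise ValidationError("phase counts must be positive")


@dataclass(frozen=True)
class FlatteningSchedule:
    """Phases of the flattening loop: many short runs, a few medium refinement
    runs, then production runs with further refinement after each."""

    phases: tuple[FlatteningPhase, ...]

    def __post_init__(self) -> None:
        if not any(p.production for p in self.phases):
            raise ValidationError("schedule needs at least one production phase")

    @classmethod
    def default(cls) -> "FlatteningSchedule":
        """Full-scale default mirroring the short/medium/production structure."""
        return cls(
            (
                FlatteningPhase(10, 1_000),
                FlatteningPhase(10, 10_000),
                FlatteningPhase(1, 50_000, production=True),
                FlatteningPhase(1, 200_000, production=True),
                FlatteningPhase(1, 200_000, production=True),
                FlatteningPhase(1, 1_000_000, production=True),
            )
        )

    @classmethod
    def quick(cls, production_steps: int = 40_000) -> "FlatteningSchedule":
        """Reduced schedule with the same phase structure, for small systems."""
        return cls(
            (
                FlatteningPhase(8, 5_000),
                FlatteningPhase(4, 15_000),
                FlatteningPhase(1, 20_000, production=True),
                FlatteningPhase(1, production_steps, production=True),
            )
        )


@dataclass
class FlatteningLogEntry:
    phase: int
    iteration: int
    n_steps: int
    production: bool
    imbalance: float  # max |residual endpoint difference| over coordinates
    bias: BiasParameters
    profile: FreeEnergyProfile


def alf_flatten(
    topology: AlchemicalTopology,
    H: ModelHamiltonian,
    schedule: FlatteningSchedule,
    settings: SamplerSettings,
    seed: int | None = None,
    initial_bias: BiasParameters | None = None,
    bins: int = 25,
    n_boot: int = 50,
    damping: float = 0.8,
    cap: float = 5.0,
    reset: bool = True,
) -> tuple[BiasParameters, list[FlatteningLogEntry]]:
    """Run the full ALF loop from zero tunable bias.

    ``initial_bias`` may carry a structural inter-site Ψ coupling (the coupled
    2λ scheme); its linear and intra-site parts are zeroed before flattening
    begins unless ``reset=False`` (continuation from an already converged
    bias).  Fully reproducible from ``seed`` (defaults to ``settings.seed``).
    Aborts with a diagnostic if the sampled support stays degenerate through
    the entire first phase.
    """
    master = settings.seed if seed is None else seed
    if initial_bias is None:
        bias = BiasParameters.zeros(topology)
    else:
        bias = initial_bias.copy()
        if reset:
            bias.linear[:] = 0.0
            bias.intra_quad[:] = 0.0
    log: list[FlatteningLogEntry] = []
    counter = 0
    n_production_seen = 0
    state = None  # warm-start chain: each iteration continues the last
    for p_idx, phase in enumerate(schedule.phases):
        phase_degenerate = True
        for it in range(phase.n_iterations):
            counter += 1
            # record enough frames per iteration for a usable histogram
            save = min(settings.save_interval, max(1, phase.n_steps // 400))
            run_settings = settings.with_(
                n_steps=phase.n_steps,
                save_interval=save,
                seed=derive_seed(master, p_idx, it),
            )
            traj = run_trajectory(topology, H, bias, run_settings, start=state)
            state = traj.final_state
            rng = np.random.default_rng(derive_seed(master, p_idx, it, 1))
            profile = estimate_profile(
                traj, bias, bins=bins, n_boot=n_boot, rng=rng,
                temperature=settings.temperature,
            )
            phase_degenerate = phase_degenerate and profile.degenerate
            imb = profile.endpoint_imbalance()
            imbalance = float(np.nanmax(np.abs(imb))) if np.any(np.isfinite(imb)) else np.nan
            if phase.update:
                # production refinements use successively smaller steps so
                # the converged coefficients stop random-walking with the
                # per-run estimation noise
                eff = (
                    damping * (0.5 ** (n_production_seen + 1))
                    if phase.production
                    else damping
                )
                bias = update_bias(profile, bias, damping=eff, cap=cap)
            log.append(
                FlatteningLogEntry(
                    phase=p_idx,
                    iteration=it,
                    n_steps=phase.n_steps,
                    production=phase.production,
                    imbalance=imbalance,
                    bias=bias.copy(),
                    profile=profile,
                )
            )
        if phase.production:
            n_production_seen += 1
        if p_idx == 0 and phase_degenerate:
            raise RuntimeError(
                "landscape support stayed degenerate through the first "
                "flattening phase; reduce the energy gaps or lengthen the "
                "iterations"
            )
    return bias, log
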