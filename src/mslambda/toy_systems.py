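"""Reduced WRKY-like test systems with exactly known ground truth.

The bound and unbound ensembles of a transcription-factor/DNA complex are
emulated as sequence-dependent well depths: each properly paired sequence is
assigned an effective energy (kcal/mol) in each ensemble, realized through
the per-substituent energies ``h`` and inter-site couplings ``J`` of the
reduced Hamiltonian.  In the 2λ schemes a mispair penalty is added on
non-complementary (fwd, rev) substituent combinations of each base pair.

Because the composite potential is an explicit function of a handful of θ
coordinates, the exact free energy of every endstate bin is available by
dense numerical quadrature of exp(−V(θ)/k_BT); that oracle is the master
reference the sampling machinery is tested against.  The quadrature
integrates the *gauge-fixed* θ subspace (per-site zero-sum direction); the
per-site gauge mode is an independent Gaussian under the θ confinement and
cancels from every bin-mass ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .alchemical_core import (
    KB,
    DEFAULT_STEEPNESS,
    AlchemicalTopology,
    ModelHamiltonian,
    ValidationError,
    effective_quadratic_form,
)
from .alf import BiasParameters
from .sampler import DEFAULT_THETA_RESTRAINT
from .schemes import COMPLEMENT, MutationSpec, SchemeBuild, build_scheme, matched_state_filter

__all__ = [
    "ToySpec",
    "ToySystem",
    "make_toy_pair",
    "quadrature_dg",
    "quadrature_convergence",
    "theta_gap_density",
]


@dataclass(frozen=True)
class ToySpec:
    """Specification of a reduced bound/unbound system pair.

    Well-depth tables are keyed by properly paired (primary-strand) sequence
    and must cover all of them; the mispair penalty applies to the 2λ schemes
    only.
    """

    native: str
    mutants: tuple[str, ...]
    bound_depths: Mapping[str, float]
    unbound_depths: Mapping[str, float]
    mispair_penalty: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mispair_penalty < 0:
            raise ValidationError("mispair penalty must be >= 0")
        object.__setattr__(self, "mutants", tuple(self.mutants))
        object.__setattr__(self, "bound_depths", dict(self.bound_depths))
        object.__setattr__(self, "unbound_depths", dict(self.unbound_depths))

    # -- standard fixtures -------------------------------------------------

    @classmethod
    def wbox(cls) -> "ToySpec":
        """W-box → GATAAA emulation with per-mutant binding penalties.

        The bound-ensemble depths place the intermediate single-pair mutants
        at ~4 and ~2 kcal/mol and the double mutant at ~5.7 kcal/mol above
        the native well, the scale reported for this motif; the unbound DNA
        is sequence-indifferent.
        """
        return cls(
            native="GGTCAA",
            mutants=("GATAAA",),
            bound_depths={
                "GGTCAA": 0.0,
                "GATCAA": 4.0,
                "GGTAAA": 2.0,
                "GATAAA": 5.7,
            },
            unbound_depths={
                "GGTCAA": 0.0,
                "GATCAA": 0.0,
                "GGTAAA": 0.0,
                "GATAAA": 0.0,
            },
        )

    @classmethod
    def standard_two_pair(cls, mispair_penalty: float = 2.0) -> "ToySpec":
        """Symmetric two-base-pair toy used for scheme comparison."""
        seqs = ("GGTCAA", "GATCAA", "GGTAAA", "GATAAA")
        zeros = {s: 0.0 for s in seqs}
        return cls(
            native="GGTCAA",
            mutants=("GATAAA",),
            bound_depths=zeros,
            unbound_depths=dict(zeros),
            mispair_penalty=mispair_penalty,
        )

    @classmethod
    def random(
        cls, seed: int, n_positions: int = 1, depth_scale: float = 3.0
    ) -> "ToySpec":
        """Random well depths on a 1- or 2-position W-box mutation."""
        if n_positions not in (1, 2):
            raise ValidationError("random toys support 1 or 2 variant positions")
        rng = np.random.default_rng(seed)
        native = "GGTCAA"
        positions = [1, 3][:n_positions]
        alt = {"G": "A", "T": "A", "C": "A", "A": "G"}
        mutant = list(native)
        for p in positions:
            mutant[p] = alt[native[p]]
        spec_tmp = MutationSpec(native, ("".join(mutant),))
        build = build_scheme(spec_tmp)
        seqs = [build.topology.sequence_of(sel) for sel in build.topology.iter_vertices()]
        bound = {s: 0.0 for s in seqs}
        unbound = {s: 0.0 for s in seqs}
        for s in seqs:
            if s != native:
                bound[s] = float(rng.uniform(0.5, depth_scale))
                unbound[s] = float(rng.uniform(0.0, 1.0))
        return cls(
            native=native,
            mutants=("".join(mutant),),
            bound_depths=bound,
            unbound_depths=unbound,
            seed=seed,
        )


@dataclass
class ToySystem:
    """A matched bound/unbound Hamiltonian pair over one topology."""

    topology: AlchemicalTopology
    bound: ModelHamiltonian
    unbound: ModelHamiltonian
    initial_bias: BiasParameters
    spec: ToySpec
    scheme: str
    matched_sequences: tuple[str, ...]


def _depth_hamiltonian(
    build: SchemeBuild, depths: Mapping[str, float], penalty: float
) -> ModelHamiltonian:
    """Realize a sequence-level depth table as (env, h, J) on a scheme topology."""
    topo = build.topology
    spec = build.spec
    positions = build.positions
    n_pos = len(positions)
    if n_pos > 2:
        raise ValidationError(
            "depth tables with pairwise couplings support at most 2 variant positions"
        )
    matched = matched_state_filter(topo)
    labels = [topo.sequence_of(sel) for sel in matched]
    missing = [l for l in labels if l not in depths]
    if missing:
        raise ValidationError(f"well-depth table missing sequences: {missing}")

    two_lambda = bool(topo.pairing)
    # site index of the primary-strand site of position k
    primary = [2 * k if two_lambda else k for k in range(n_pos)]

    def depth_of(selection_per_pos: Sequence[int]) -> float:
        s = list(spec.native)
        for k, p in enumerate(positions):
            s[p] = topo.sites[primary[k]].substituents[selection_per_pos[k]]
        return float(depths["".join(s)])

    n = topo.n_coords
    h = np.zeros(n)
    J = np.zeros((n, n))
    ref = (0,) * n_pos
    env = depth_of(ref)
    for k in range(n_pos):
        s = primary[k]
        for i in range(topo.sites[s].n):
            sel = list(ref)
            sel[k] = i
            h[topo.coord_index(s, i)] = depth_of(sel) - env
    if n_pos == 2:
        s, t = primary
        for i in range(topo.sites[s].n):
            for j in range(topo.sites[t].n):
                val = (
                    depth_of((i, j))
                    - depth_of((i, 0))
                    - depth_of((0, j))
                    + env
                )
                a, b = topo.coord_index(s, i), topo.coord_index(t, j)
                J[a, b] = J[b, a] = val
    if two_lambda and penalty != 0.0:
        for k in range(n_pos):
            s_fwd, s_rev = 2 * k, 2 * k + 1
            for i in range(topo.sites[s_fwd].n):
                for j in range(topo.sites[s_rev].n):
                    base_f = topo.sites[s_fwd].substituents[i]
                    base_r = topo.sites[s_rev].substituents[j]
                    if COMPLEMENT[base_f] != base_r:
                        a = topo.coord_index(s_fwd, i)
                        b = topo.coord_index(s_rev, j)
                        J[a, b] = J[b, a] = penalty
    return ModelHamiltonian(topo, env_energy=env, h=h, J=J)


def make_toy_pair(
    spec: ToySpec, scheme: str = "one_lambda_per_pair"
) -> ToySystem:
    """Build the bound/unbound Hamiltonian pair for a toy spec under a scheme.

    Sequence-level well depths are realized exactly: the energy of every
    properly paired vertex equals its table entry, and in the 2λ schemes
    every mispaired combination additionally pays the mispair penalty per
    mispaired position.  The exact ΔΔG of every mutant is then available
    through :func:`quadrature_dg`.
    """
    mspec = MutationSpec(
        spec.native, spec.mutants, scheme=scheme, psi0=max(spec.mispair_penalty, 1.0)
    )
    build = build_scheme(mspec)
    bound = _depth_hamiltonian(build, spec.bound_depths, spec.mispair_penalty)
    unbound = _depth_hamiltonian(build, spec.unbound_depths, spec.mispair_penalty)
    matched = tuple(
        build.topology.sequence_of(sel) for sel in matched_state_filter(build.topology)
    )
    return ToySystem(
        topology=build.topology,
        bound=bound,
        unbound=unbound,
        initial_bias=build.initial_bias,
        spec=spec,
        scheme=mspec.scheme,
        matched_sequences=matched,
    )


# ---------------------------------------------------------------------------
# quadrature oracle
# ---------------------------------------------------------------------------


def _simpson_weights(n: int, h: float) -> np.ndarray:
    if n < 3 or n % 2 == 0:
        raise ValidationError("Simpson quadrature needs an odd number of points >= 3")
    w = np.ones(n)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w * (h / 3.0)


def _default_grid(dim: int) -> int:
    return {1: 401, 2: 161, 3: 61, 4: 41}[dim]


def _site_quantities(
    c: np.ndarray, steepness: float
) -> tuple[np.ndarray, np.ndarray]:
    """λ components (λ0, λ1) of a two-substituent site along its gap coordinate."""
    z = steepness * np.sqrt(2.0) * c
    lam0 = 1.0 / (1.0 + np.exp(-z))
    return lam0, 1.0 - lam0


def quadrature_dg(
    H: ModelHamiltonian,
    topology: AlchemicalTopology,
    bias: BiasParameters | None = None,
    temperature: float = 298.0,
    lambda_c: float = 0.99,
    grid: int | None = None,
    theta_restraint: float = DEFAULT_THETA_RESTRAINT,
    steepness: float = DEFAULT_STEEPNESS,
    reference: str | None = None,
    bias_correction: bool = True,
) -> dict[str, float]:
    """Exact per-sequence ΔG by dense quadrature of the Boltzmann weight.

    For each endstate the Boltzmann mass is integrated over its λc bin in the
    gauge-fixed θ subspace (Simpson's rule on an exactly aligned product
    grid), and ΔG = −kT ln of the bin-mass ratio with the same linear-bias
    correction as the population estimator.  Deliberately small-scale:
    two-substituent sites only and at most 4 gauge-fixed dimensions.
    """
    if any(site.n != 2 for site in topology.sites):
        raise ValidationError("quadrature oracle supports two-substituent sites only")
    dim = topology.n_sites
    if dim > 4:
        raise ValidationError("quadrature oracle supports at most 4 sites")
    if theta_restraint <= 0:
        raise ValidationError("quadrature needs a positive theta restraint")
    kT = KB * temperature
    g = _default_grid(dim) if grid is None else int(grid)
    if g % 2 == 0:
        g += 1

    env, cvec, A = effective_quadratic_form(H, bias)
    sigma = np.sqrt(kT / theta_restraint)
    L = max(8.0, 7.0 * sigma)
    # bin boundary in the per-site gap coordinate: λ >= λc
    c_star = np.log(lambda_c / (1.0 - lambda_c)) / (steepness * np.sqrt(2.0))
    if c_star >= L:
        raise ValidationError("lambda_c bin lies outside the integration domain")

    def bin_mass(selection: Sequence[int]) -> float:
        axes = []
        site_e = []
        lams = []
        weights = []
        for s, pick in enumerate(selection):
            lo, hi = (c_star, L) if pick == 0 else (-L, -c_star)
            c = np.linspace(lo, hi, g)
            lam0, lam1 = _site_quantities(c, steepness)
            lam = np.stack([lam0, lam1], axis=1)  # (g, 2)
            sl = topology.site_slice(s)
            block = A[sl, sl]
            e = (
                lam @ cvec[sl]
                + lam0 * lam1 * (block[0, 1] + block[1, 0])
                + 0.5 * theta_restraint * c**2
            )
            axes.append(c)
            site_e.append(e)
            lams.append(lam)
            weights.append(_simpson_weights(g, c[1] - c[0]))
        shape = (g,) * dim
        E = np.zeros(shape)
        for s in range(dim):
            sh = [1] * dim
            sh[s] = g
            E += site_e[s].reshape(sh)
        for s in range(dim):
            for t in range(s + 1, dim):
                sl_s, sl_t = topology.site_slice(s), topology.site_slice(t)
                cross = lams[s] @ A[sl_s, sl_t] @ lams[t].T  # (g, g)
                sh = [1] * dim
                sh[s] = g
                sh[t] = g
                E += cross.reshape(sh)
        W = np.exp(-(E - E.min()) / kT)
        for s in range(dim):
            sh = [1] * dim
            sh[s] = g
            W = W * weights[s].reshape(sh)
        return float(W.sum() * np.exp(-E.min() / kT))

    masses = {}
    for sel in topology.iter_vertices():
        masses[topology.sequence_of(sel)] = (bin_mass(sel), sel)
    if reference is None:
        reference = topology.sequence_of((0,) * dim)
    m_ref, sel_ref = masses[reference]
    b_ref = (
        bias.vertex_linear_energy(sel_ref) if (bias is not None and bias_correction) else 0.0
    )
    out = {}
    for seq, (m, sel) in masses.items():
        b_m = (
            bias.vertex_linear_energy(sel)
            if (bias is not None and bias_correction)
            else 0.0
        )
        out[seq] = -kT * np.log(m / m_ref) - (b_m - b_ref)
    return out


def quadrature_convergence(
    H: ModelHamiltonian,
    topology: AlchemicalTopology,
    grid: int,
    **kwargs,
) -> float:
    """Max |ΔG(grid) − ΔG(2·grid)| over sequences — the doubling check."""
    a = quadrature_dg(H, topology, grid=grid, **kwargs)
    b = quadrature_dg(H, topology, grid=2 * grid + 1, **kwargs)
    return max(abs(a[k] - b[k]) for k in a)


def theta_gap_density(
    H: ModelHamiltonian,
    topology: AlchemicalTopology,
    bias: BiasParameters | None = None,
    temperature: float = 298.0,
    theta_restraint: float = DEFAULT_THETA_RESTRAINT,
    steepness: float = DEFAULT_STEEPNESS,
    grid: int = 2001,
    span: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact marginal density of the θ gap d = θ_s0 − θ_s1 of a 1-site system.

    Returns (d, pdf) with the pdf normalized by trapezoidal rule; the gauge
    mode integrates out exactly.  Used as the Boltzmann-fidelity reference
    for the sampler.
    """
    if topology.n_sites != 1 or topology.sites[0].n != 2:
        raise ValidationError("theta_gap_density is defined for one 2-substituent site")
    kT = KB * temperature
    env, cvec, A = effective_quadratic_form(H, bias)
    sigma = np.sqrt(kT / theta_restraint)
    if span is None:
        span = max(10.0, 7.0 * sigma * np.sqrt(2.0))
    d = np.linspace(-span, span, grid)
    lam0 = 1.0 / (1.0 + np.exp(-steepness * d))
    lam1 = 1.0 - lam0
    e = (
        cvec[0] * lam0
        + cvec[1] * lam1
        + lam0 * lam1 * (A[0, 1] + A[1, 0])
        + 0.25 * theta_restraint * d**2
    )
    p = np.exp(-(e - e.min()) / kT)
    p /= np.trapezoid(p, d)
    return d, p
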