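"""Alchemical state space and the reduced composite potential.

Multisite λ-dynamics treats the alchemical coupling variables λ_si (site *s*,
substituent *i*) as dynamical coordinates.  At a physical endstate exactly one
substituent per site is fully coupled (λ_si = 1) and all others are off.  In
between, the potential interpolates bilinearly:

    V(λ) = E_env + Σ_s Σ_i λ_si h_si
         + Σ_s Σ_{t>s} Σ_i Σ_j λ_si λ_tj J_{si,tj}
         + V_bias(λ)

Here the Cartesian force-field terms of an all-atom engine are collapsed into
scalar effective energies: ``h_si`` stands for the substituent–environment plus
substituent self interaction and ``J_{si,tj}`` for the inter-site
substituent–substituent interaction.  This preserves the full alchemical
structure (linear λ scaling of environment terms, bilinear inter-site terms)
while making exact brute-force and quadrature oracles feasible.

The constraints Σ_i λ_si = 1, λ_si ∈ [0, 1] are maintained *implicitly* by
propagating unconstrained coordinates θ_si and mapping them through a per-site
exponential normalization (softmax) with a steepness constant:

    λ_si = exp(α θ_si) / Σ_j exp(α θ_sj)

which satisfies the constraints exactly by construction.  All energies are in
kcal/mol, temperatures in kelvin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "KB",
    "DEFAULT_STEEPNESS",
    "Site",
    "AlchemicalTopology",
    "ThetaState",
    "LambdaState",
    "ModelHamiltonian",
    "ValidationError",
    "theta_to_lambda",
    "lambda_from_theta_array",
    "potential_energy",
    "potential_gradient_theta",
    "effective_quadratic_form",
]

#: Boltzmann constant in kcal/mol/K, used consistently everywhere.
KB = 0.0019872041

#: Default steepness α of the softmax implicit-constraint transform.
DEFAULT_STEEPNESS = 5.5


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass(frozen=True)
class Site:
    """One alchemical site: a label and its substituent labels (N_s >= 2)."""

    label: str
    substituents: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.substituents) < 2:
            raise ValidationError(
                f"site {self.label!r} needs at least 2 substituents, "
                f"got {len(self.substituents)}"
            )
        if len(set(self.substituents)) != len(self.substituents):
            raise ValidationError(f"duplicate substituent labels at site {self.label!r}")

    @property
    def n(self) -> int:
        return len(self.substituents)


class AlchemicalTopology:
    """Sites, substituents and base-pairing structure of the λ coordinate space.

    Coordinates are stored flat, site-major / substituent-minor.  ``pairing``
    optionally links two sites as a Watson–Crick pair (used by the 2λ schemes);
    it is symmetric and involutive.  ``sequence_map`` maps each vertex
    selection (one substituent index per site) to a sequence label and must be
    total over the ∏_s N_s combinations; by default it joins substituent
    labels in site order.
    """

    def __init__(
        self,
        sites: Sequence[Site | tuple[str, Sequence[str]]],
        pairing: Mapping[int, int] | None = None,
        sequence_map: Mapping[tuple[int, ...], str] | None = None,
    ) -> None:
        norm: list[Site] = []
        for s in sites:
            norm.append(s if isinstance(s, Site) else Site(s[0], tuple(s[1])))
        if not norm:
            raise ValidationError("topology needs at least one site")
        labels = [s.label for s in norm]
        if len(set(labels)) != len(labels):
            raise ValidationError("site labels must be unique")
        self.sites: tuple[Site, ...] = tuple(norm)

        pairing = dict(pairing or {})
        for a, b in pairing.items():
            if not (0 <= a < len(norm) and 0 <= b < len(norm)) or a == b:
                raise ValidationError(f"invalid pairing entry {a} -> {b}")
            if pairing.get(b) != a:
                raise ValidationError("pairing must be symmetric and involutive")
        self.pairing: dict[int, int] = pairing

        counts = [s.n for s in norm]
        self._starts = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)

        if sequence_map is None:
            sequence_map = {
                sel: "".join(self.sites[s].substituents[i] for s, i in enumerate(sel))
                for sel in self.iter_vertices()
            }
        else:
            sequence_map = dict(sequence_map)
            missing = [sel for sel in self.iter_vertices() if sel not in sequence_map]
            if missing:
                raise ValidationError(
                    f"sequence_map is not total: {len(missing)} vertex "
                    f"combinations missing (e.g. {missing[0]})"
                )
        self.sequence_map: dict[tuple[int, ...], str] = sequence_map

    # -- structure ---------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_coords(self) -> int:
        return int(self._starts[-1])

    @property
    def site_starts(self) -> np.ndarray:
        """Start offsets of each site's block in the flat coordinate vector."""
        return self._starts[:-1]

    @property
    def site_stops(self) -> np.ndarray:
        return self._starts[1:]

    def site_slice(self, s: int) -> slice:
        return slice(int(self._starts[s]), int(self._starts[s + 1]))

    def coord_index(self, s: int, i: int) -> int:
        if not 0 <= i < self.sites[s].n:
            raise ValidationError(f"substituent index {i} out of range at site {s}")
        return int(self._starts[s]) + i

    def site_of_coord(self, k: int) -> tuple[int, int]:
        s = int(np.searchsorted(self._starts, k, side="right")) - 1
        return s, k - int(self._starts[s])

    def coord_labels(self) -> list[str]:
        """Flat coordinate labels ``site:substituent`` in site-major order."""
        return [
            f"{site.label}:{sub}" for site in self.sites for sub in site.substituents
        ]

    # -- vertices ----------------------------------------------------------

    def iter_vertices(self) -> Iterator[tuple[int, ...]]:
        """All ∏_s N_s vertex selections, site-major odometer order."""

        def rec(prefix: tuple[int, ...], s: int) -> Iterator[tuple[int, ...]]:
            if s == self.n_sites:
                yield prefix
                return
            for i in range(self.sites[s].n):
                yield from rec(prefix + (i,), s + 1)

        yield from rec((), 0)

    def vertex_lambda(self, selection: Sequence[int]) -> np.ndarray:
        """λ vector of the endstate selecting substituent ``selection[s]`` per site."""
        if len(selection) != self.n_sites:
            raise ValidationError("selection length must equal the number of sites")
        lam = np.zeros(self.n_coords)
        for s, i in enumerate(selection):
            lam[self.coord_index(s, int(i))] = 1.0
        return lam

    def sequence_of(self, selection: Sequence[int]) -> str:
        return self.sequence_map[tuple(int(i) for i in selection)]

    def intra_site_mask(self) -> np.ndarray:
        """Boolean (n, n) mask of same-site coordinate pairs."""
        n = self.n_coords
        mask = np.zeros((n, n), dtype=bool)
        for s in range(self.n_sites):
            sl = self.site_slice(s)
            mask[sl, sl] = True
        return mask

    def paired_block_mask(self) -> np.ndarray:
        """Boolean (n, n) mask of coordinate pairs on Watson–Crick paired sites."""
        n = self.n_coords
        mask = np.zeros((n, n), dtype=bool)
        for a, b in self.pairing.items():
            mask[self.site_slice(a), self.site_slice(b)] = True
        return mask

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"AlchemicalTopology({self.n_sites} sites, "
            f"{self.n_coords} coords, {len(self.pairing) // 2} pairs)"
        )


def _check_finite(name: str, arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite entries")


@dataclass
class ThetaState:
    """Unconstrained coordinates realizing the implicit constraints.

    One real θ per (site, substituent) plus matching velocities.  The softmax
    transform is invariant to a per-site constant shift of θ, so the per-site
    mean of θ is a gauge degree of freedom with no effect on λ.
    """

    topology: AlchemicalTopology
    theta: np.ndarray
    velocity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (self.topology.n_coords,):
            raise ValidationError(
                f"theta shape {self.theta.shape} does not match topology "
                f"({self.topology.n_coords} coordinates)"
            )
        _check_finite("theta", self.theta)
        if self.velocity is None:
            self.velocity = np.zeros_like(self.theta)
        else:
            self.velocity = np.asarray(self.velocity, dtype=float)
            if self.velocity.shape != self.theta.shape:
                raise ValidationError("velocity shape must match theta")
            _check_finite("velocity", self.velocity)

    def copy(self) -> "ThetaState":
        return ThetaState(self.topology, self.theta.copy(), self.velocity.copy())


@dataclass
class LambdaState:
    """Constrained alchemical coordinates: λ_si in [0,1], Σ_i λ_si = 1 per site."""

    topology: AlchemicalTopology
    lam: np.ndarray

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        if self.lam.shape != (self.topology.n_coords,):
            raise ValidationError("lambda shape does not match topology")
        _check_finite("lambda", self.lam)
        if np.any(self.lam < -1e-12) or np.any(self.lam > 1 + 1e-12):
            raise ValidationError("lambda entries must lie in [0, 1]")
        for s in range(self.topology.n_sites):
            tot = self.lam[self.topology.site_slice(s)].sum()
            if abs(tot - 1.0) > 1e-12:
                raise ValidationError(
                    f"lambda at site {s} sums to {tot!r}, expected 1"
                )


@dataclass
class ModelHamiltonian:
    """Effective energies replacing the force-field terms of the composite potential.

    ``env_energy`` is the environment self-term (a constant), ``h[k]`` the
    combined substituent–environment and substituent self energy of flat
    coordinate ``k``, and ``J`` the symmetric inter-site coupling matrix;
    intra-site blocks of ``J`` are identically zero because only one
    substituent per site is ever physical.
    """

    topology: AlchemicalTopology
    env_energy: float = 0.0
    h: np.ndarray | None = None
    J: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.topology.n_coords
        self.env_energy = float(self.env_energy)
        self.h = np.zeros(n) if self.h is None else np.asarray(self.h, dtype=float)
        self.J = np.zeros((n, n)) if self.J is None else np.asarray(self.J, dtype=float)
        if self.h.shape != (n,):
            raise ValidationError("h shape does not match topology")
        if self.J.shape != (n, n):
            raise ValidationError("J shape does not match topology")
        _check_finite("h", self.h)
        _check_finite("J", self.J)
        if not np.allclose(self.J, self.J.T, atol=1e-12):
            raise ValidationError("J must be symmetric under (s,i) <-> (t,j) exchange")
        if np.any(self.J[self.topology.intra_site_mask()] != 0.0):
            raise ValidationError("intra-site J entries must be identically zero")

    def vertex_energy(self, selection: Sequence[int]) -> float:
        """Exact endstate energy at a vertex (no bias)."""
        lam = self.topology.vertex_lambda(selection)
        return float(self.env_energy + self.h @ lam + 0.5 * lam @ self.J @ lam)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def lambda_from_theta_array(
    theta: np.ndarray,
    topology: AlchemicalTopology,
    steepness: float = DEFAULT_STEEPNESS,
) -> np.ndarray:
    """Per-site softmax of ``steepness * theta`` (array-level workhorse).

    Numerically stable via per-site max subtraction.  λ can underflow to
    exactly 0 for very negative θ, which is acceptable.
    """
    if steepness <= 0:
        raise ValidationError("steepness must be positive")
    theta = np.asarray(theta, dtype=float)
    _check_finite("theta", theta)
    lam = np.empty_like(theta)
    for s in range(topology.n_sites):
        sl = topology.site_slice(s)
        z = steepness * theta[sl]
        z = z - z.max()
        e = np.exp(z)
        lam[sl] = e / e.sum()
    return lam


def theta_to_lambda(
    theta: ThetaState, steepness: float = DEFAULT_STEEPNESS
) -> LambdaState:
    """Map unconstrained θ to constrained λ through the implicit-constraint transform."""
    lam = lambda_from_theta_array(theta.theta, theta.topology, steepness)
    return LambdaState(theta.topology, lam)


def effective_quadratic_form(
    H: ModelHamiltonian, bias
) -> tuple[float, np.ndarray, np.ndarray]:
    """Collapse Hamiltonian plus bias into ``V = const + c·λ + ½ λᵀ A λ``.

    The bias contributes −b_si to the linear part, 2ψ to the quadratic part
    (the intra-site term is summed over ordered pairs i ≠ j) and −Ψ to the
    quadratic part (the inter-site coupling is counted once per site pair).
    Used by the gradient, the sampler kernel and the quadrature oracle so all
    three share one definition of the energy.
    """
    if bias is None:
        return H.env_energy, H.h.copy(), H.J.copy()
    if bias.topology is not H.topology and bias.topology.n_coords != H.topology.n_coords:
        raise ValidationError("bias and Hamiltonian topologies are inconsistent")
    c = H.h - bias.linear
    A = H.J + 2.0 * bias.intra_quad - bias.inter_coupling
    return H.env_energy, c, A


def potential_energy(lam: LambdaState, H: ModelHamiltonian, bias=None) -> float:
    """Composite potential V(λ) = E_env + Σ λh + Σ λλJ + V_bias(λ), in kcal/mol."""
    if lam.topology.n_coords != H.topology.n_coords:
        raise ValidationError("lambda and Hamiltonian dimensions are inconsistent")
    x = lam.lam
    v = H.env_energy + float(H.h @ x) + 0.5 * float(x @ H.J @ x)
    if bias is not None:
        from .alf import bias_energy  # deferred: alf depends on this module

        v += bias_energy(lam, bias)
    return v


def _dV_dlambda(lam: np.ndarray, H: ModelHamiltonian, bias) -> np.ndarray:
    _, c, A = effective_quadratic_form(H, bias)
    return c + A @ lam


def potential_gradient_theta(
    theta: ThetaState,
    H: ModelHamiltonian,
    bias=None,
    steepness: float = DEFAULT_STEEPNESS,
) -> np.ndarray:
    """Analytic ∂V/∂θ via the softmax Jacobian chain rule.

    With g = ∂V/∂λ, per site: ∂V/∂θ_si = α λ_si (g_si − Σ_j λ_sj g_sj).
    """
    topo = theta.topology
    lam = lambda_from_theta_array(theta.theta, topo, steepness)
    g = _dV_dlambda(lam, H, bias)
    grad = np.empty_like(lam)
    for s in range(topo.n_sites):
        sl = topo.site_slice(s)
        ls, gs = lam[sl], g[sl]
        grad[sl] = steepness * ls * (gs - float(ls @ gs))
    return grad
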