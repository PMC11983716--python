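"""Langevin dynamics on the unconstrained θ coordinates.

The λ coordinates are propagated indirectly: BAOAB Langevin dynamics on θ at
fixed temperature, with λ = softmax(α θ) recorded along the way.  Two
deliberate departures from an all-atom engine:

* **Model units.**  θ carries unit mass and the timestep/friction are in
  model units; the fs/ns timescales of a molecular engine do not transfer to
  the reduced Hamiltonian.  Defaults (dt = 0.01, friction = 2) are tuned so a
  symmetric two-substituent site yields a usable endstate transition rate
  (≥ 0.1 per 1000 steps).

* **θ confinement.**  V(λ(θ)) is flat on the plateaus where λ has saturated,
  so the Boltzmann measure over θ would not be normalizable.  A weak harmonic
  restraint ½ k_θ |θ|² confines θ.  The per-site gauge direction (softmax is
  invariant to a per-site constant shift of θ) is thereby bounded too and its
  Gaussian factor cancels exactly from every population ratio; the quadrature
  oracle integrates the identical restrained potential, so estimator and
  oracle always refer to the same ensemble.

The Boltzmann constant is KB = 0.0019872041 kcal/mol/K everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .alchemical_core import (
    KB,
    DEFAULT_STEEPNESS,
    AlchemicalTopology,
    ModelHamiltonian,
    ThetaState,
    ValidationError,
    effective_quadratic_form,
)
from ._kernels import baoab_chunk

__all__ = [
    "DEFAULT_THETA_RESTRAINT",
    "SamplerSettings",
    "LambdaTrajectory",
    "step_langevin",
    "run_trajectory",
    "write_trajectory",
    "read_trajectory",
    "derive_seed",
]

#: Default θ-confinement spring constant (kcal/mol per θ² unit).
DEFAULT_THETA_RESTRAINT = 0.3

_CHUNK = 100_000  # noise is drawn in fixed chunks so seeding is layout-stable


@dataclass(frozen=True)
class SamplerSettings:
    """Integrator settings (model units; temperature in kelvin)."""

    timestep: float = 0.01
    friction: float = 2.0
    temperature: float = 298.0
    n_steps: int = 100_000
    save_interval: int = 50
    seed: int = 0
    mass: float = 1.0
    theta_restraint: float = DEFAULT_THETA_RESTRAINT
    steepness: float = DEFAULT_STEEPNESS

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValidationError("timestep must be positive")
        if self.friction < 0:
            raise ValidationError("friction must be non-negative")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        if self.n_steps < 1 or self.save_interval < 1:
            raise ValidationError("n_steps and save_interval must be >= 1")
        if self.mass <= 0:
            raise ValidationError("mass must be positive")
        if self.theta_restraint < 0:
            raise ValidationError("theta_restraint must be non-negative")

    @property
    def kT(self) -> float:
        return KB * self.temperature

    def with_(self, **kw) -> "SamplerSettings":
        return replace(self, **kw)


@dataclass
class LambdaTrajectory:
    """Time series of λ vectors (site-major, substituent-minor) with metadata."""

    topology: AlchemicalTopology
    frames: np.ndarray  # (n_frames, n_coords)
    steps: np.ndarray  # (n_frames,), strictly increasing step indices
    settings: SamplerSettings | None = None
    replica_id: int = 0
    theta_frames: np.ndarray | None = None
    #: final θ/velocity state, for continuation runs (not serialized)
    final_state: ThetaState | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.steps = np.asarray(self.steps, dtype=np.int64)
        if self.frames.ndim != 2 or self.frames.shape[1] != self.topology.n_coords:
            raise ValidationError("frame width does not match topology")
        if self.steps.shape != (self.frames.shape[0],):
            raise ValidationError("steps length must equal frame count")
        if self.frames.shape[0] > 1 and np.any(np.diff(self.steps) <= 0):
            raise ValidationError("step indices must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def model_time(self) -> float:
        """Total model time spanned by the recorded frames."""
        if self.settings is None or self.n_frames == 0:
            return float(self.n_frames)
        return float(self.steps[-1]) * self.settings.timestep


def derive_seed(master: int, *indices: int) -> int:
    """Derive an independent child seed from a master seed and counters.

    Splitmix64-style mixing; avoids correlated streams across replicas and
    flattening iterations.  The result is kept below 2**31.
    """
    x = (int(master) & 0xFFFFFFFFFFFFFFFF) ^ 0x9E3779B97F4A7C15
    for idx in indices:
        x = (x + 0x9E3779B97F4A7C15 + (int(idx) << 1)) & 0xFFFFFFFFFFFFFFFF
        x ^= x >> 30
        x = (x * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
        x ^= x >> 27
        x = (x * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
        x ^= x >> 31
    return int(x % (2**31))


def _kernel_args(topology: AlchemicalTopology, H: ModelHamiltonian, bias):
    _, c, A = effective_quadratic_form(H, bias)
    return (
        np.ascontiguousarray(topology.site_starts),
        np.ascontiguousarray(topology.site_stops),
        np.ascontiguousarray(c, dtype=float),
        np.ascontiguousarray(A, dtype=float),
    )


def step_langevin(
    state: ThetaState,
    H: ModelHamiltonian,
    bias,
    settings: SamplerSettings,
    rng: np.random.Generator,
) -> ThetaState:
    """One BAOAB update of θ and its velocity; returns a new state.

    The RNG is consumed deterministically (one unit normal per coordinate per
    step), so identical seeds and inputs give bit-identical successors.
    """
    starts, stops, c, A = _kernel_args(state.topology, H, bias)
    theta = state.theta.copy()
    vel = state.velocity.copy()
    noise = rng.standard_normal((1, theta.shape[0]))
    frames = np.empty((1, theta.shape[0]))
    tframes = np.empty((1, theta.shape[0]))
    baoab_chunk(
        theta, vel, noise, starts, stops, c, A,
        settings.steepness, settings.theta_restraint,
        settings.timestep, settings.friction, settings.kT, settings.mass,
        2, 0, frames, tframes, False, 0,
    )
    return ThetaState(state.topology, theta, vel)


def run_trajectory(
    topology: AlchemicalTopology,
    H: ModelHamiltonian,
    bias,
    settings: SamplerSettings,
    start: ThetaState | None = None,
    replica_id: int = 0,
    record_theta: bool = False,
) -> LambdaTrajectory:
    """Integrate ``settings.n_steps`` steps, recording λ every ``save_interval``.

    Initial θ is standard normal from the seeded RNG unless ``start`` is
    supplied; initial velocities are Maxwell–Boltzmann at the target
    temperature.  A non-finite coordinate aborts with a diagnostic naming the
    step at which it occurred.
    """
    rng = np.random.default_rng(settings.seed)
    n = topology.n_coords
    if start is None:
        theta = rng.standard_normal(n)
    else:
        theta = start.theta.copy()
    vel = rng.standard_normal(n) * np.sqrt(settings.kT / settings.mass)
    if start is not None and start.velocity is not None and np.any(start.velocity):
        vel = start.velocity.copy()

    starts, stops, c, A = _kernel_args(topology, H, bias)
    n_frames = settings.n_steps // settings.save_interval
    frames = np.empty((max(n_frames, 1), n))
    theta_frames = np.empty((max(n_frames, 1), n)) if record_theta else np.empty((1, n))

    n_saved = 0
    done = 0
    while done < settings.n_steps:
        m = min(_CHUNK, settings.n_steps - done)
        noise = rng.standard_normal((m, n))
        n_saved, bad_step = baoab_chunk(
            theta, vel, noise, starts, stops, c, A,
            settings.steepness, settings.theta_restraint,
            settings.timestep, settings.friction, settings.kT, settings.mass,
            settings.save_interval, done, frames, theta_frames,
            record_theta, n_saved,
        )
        if bad_step:
            raise FloatingPointError(
                f"non-finite energy/coordinate encountered at step {bad_step}"
            )
        done += m

    steps = (np.arange(n_saved) + 1) * settings.save_interval
    return LambdaTrajectory(
        topology=topology,
        frames=frames[:n_saved].copy(),
        steps=steps,
        settings=settings,
        replica_id=replica_id,
        theta_frames=theta_frames[:n_saved].copy() if record_theta else None,
        final_state=ThetaState(topology, theta.copy(), vel.copy()),
    )


# ---------------------------------------------------------------------------
# trajectory files: delimited text, one row per saved frame
# ---------------------------------------------------------------------------


def write_trajectory(traj: LambdaTrajectory, path: str | Path) -> None:
    """Write a λ trajectory as delimited text (10 significant digits).

    Header names the columns ``step, site:substituent...`` in site-major
    order; the reader/writer pair round-trips bit-exactly in decimal.
    """
    path = Path(path)
    cols = ["step"] + traj.topology.coord_labels()
    df = pd.DataFrame(
        np.column_stack([traj.steps.astype(float), traj.frames]), columns=cols
    )
    df["step"] = df["step"].astype(np.int64)
    df.to_csv(path, index=False, float_format="%.10g")


def read_trajectory(
    path: str | Path,
    topology: AlchemicalTopology,
    settings: SamplerSettings | None = None,
    replica_id: int = 0,
) -> LambdaTrajectory:
    """Read a λ trajectory written by :func:`write_trajectory`."""
    df = pd.read_csv(path)
    expected = ["step"] + topology.coord_labels()
    if list(df.columns) != expected:
        raise ValidationError(
            f"trajectory columns {list(df.columns)} do not match topology "
            f"(expected {expected})"
        )
    return LambdaTrajectory(
        topology=topology,
        frames=df[expected[1:]].to_numpy(dtype=float),
        steps=df["step"].to_numpy(dtype=np.int64),
        settings=settings,
        replica_id=replica_id,
    )
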