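"""Configuration and parameter serialization (human-readable YAML).

Bias parameters round-trip exactly in decimal because floats are emitted via
``repr`` (shortest representation that parses back to the same double).
Schema of the run configuration::

    mutation:
      native: GGTCAA
      mutants: [GATAAA]
      scheme: one_lambda_per_pair   # aliases: 1l, 2l, coupled2l
      psi0: 2.0                     # coupled scheme only, kcal/mol
    toy:
      bound_depths:   {GGTCAA: 0.0, GATAAA: 5.7, ...}   # kcal/mol
      unbound_depths: {GGTCAA: 0.0, ...}
      mispair_penalty: 2.0
    sampler:
      timestep: 0.01       # model time
      friction: 2.0        # inverse model time
      temperature: 298.0   # kelvin
      save_interval: 50
      theta_restraint: 0.3
      steepness: 5.5
    schedule:
      flatten: [[8, 5000], [4, 15000]]  # [iterations, steps] phases
      production: [40000]               # steps of each production phase
    produce: {n_steps: 100000}
    estimator: {lambda_c: 0.99, n_boot: 50}
    replicas: 5
    seed: 1
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .alchemical_core import AlchemicalTopology, ValidationError
from .alf import BiasParameters, FlatteningPhase, FlatteningSchedule
from .sampler import SamplerSettings
from .toy_systems import ToySpec, ToySystem, make_toy_pair

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "save_bias",
    "load_bias",
    "config_hash",
]


def _float(x) -> float:
    return float(x)


@dataclass
class RunConfig:
    """Parsed run configuration with defaults applied."""

    toy_spec: ToySpec
    scheme: str
    schedule: FlatteningSchedule
    sampler: SamplerSettings
    produce_steps: int
    lambda_c: float
    n_boot: int
    replicas: int
    seed: int
    raw: dict

    def build_system(self) -> ToySystem:
        return make_toy_pair(self.toy_spec, self.scheme)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return parse_config(raw)


def parse_config(raw: dict) -> RunConfig:
    try:
        mut = raw["mutation"]
        toy = raw["toy"]
    except KeyError as e:  # pragma: no cover - defensive
        raise ValidationError(f"configuration missing section {e}") from e
    toy_spec = ToySpec(
        native=mut["native"],
        mutants=tuple(mut["mutants"]),
        bound_depths={k: _float(v) for k, v in toy["bound_depths"].items()},
        unbound_depths={k: _float(v) for k, v in toy["unbound_depths"].items()},
        mispair_penalty=_float(toy.get("mispair_penalty", 2.0)),
        seed=int(raw.get("seed", 0)),
    )
    samp = raw.get("sampler", {})
    seed = int(raw.get("seed", 0))
    settings = SamplerSettings(
        timestep=_float(samp.get("timestep", 0.01)),
        friction=_float(samp.get("friction", 2.0)),
        temperature=_float(samp.get("temperature", 298.0)),
        n_steps=int(samp.get("n_steps", 100_000)),
        save_interval=int(samp.get("save_interval", 50)),
        seed=seed,
        mass=_float(samp.get("mass", 1.0)),
        theta_restraint=_float(samp.get("theta_restraint", 0.3)),
        steepness=_float(samp.get("steepness", 5.5)),
    )
    sched_raw = raw.get("schedule", {})
    phases = [
        FlatteningPhase(int(it), int(steps))
        for it, steps in sched_raw.get("flatten", [[8, 5000], [4, 15000]])
    ]
    for steps in sched_raw.get("production", [40_000]):
        phases.append(FlatteningPhase(1, int(steps), production=True))
    est = raw.get("estimator", {})
    return RunConfig(
        toy_spec=toy_spec,
        scheme=mut.get("scheme", "one_lambda_per_pair"),
        schedule=FlatteningSchedule(tuple(phases)),
        sampler=settings,
        produce_steps=int(raw.get("produce", {}).get("n_steps", 100_000)),
        lambda_c=_float(est.get("lambda_c", 0.99)),
        n_boot=int(est.get("n_boot", 50)),
        replicas=int(raw.get("replicas", 5)),
        seed=seed,
        raw=raw,
    )


def save_config(raw: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


def config_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# bias files
# ---------------------------------------------------------------------------


def save_bias(bias: BiasParameters, path: str | Path) -> None:
    """Serialize bias coefficients to a structured text file (decimal exact)."""
    topo = bias.topology
    labels = topo.coord_labels()
    doc: dict = {
        "linear": {labels[k]: repr(float(bias.linear[k])) for k in range(len(labels))},
        "intra_quad": [],
        "inter_coupling": [],
    }
    n = topo.n_coords
    for a in range(n):
        for b in range(a + 1, n):
            if bias.intra_quad[a, b] != 0.0:
                doc["intra_quad"].append(
                    {"i": labels[a], "j": labels[b], "value": repr(float(bias.intra_quad[a, b]))}
                )
            if bias.inter_coupling[a, b] != 0.0:
                doc["inter_coupling"].append(
                    {"i": labels[a], "j": labels[b], "value": repr(float(bias.inter_coupling[a, b]))}
                )
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_bias(path: str | Path, topology: AlchemicalTopology) -> BiasParameters:
    doc = yaml.safe_load(Path(path).read_text())
    labels = {lab: k for k, lab in enumerate(topology.coord_labels())}
    n = topology.n_coords
    linear = np.zeros(n)
    for lab, val in doc.get("linear", {}).items():
        linear[labels[lab]] = float(val)
    intra = np.zeros((n, n))
    for ent in doc.get("intra_quad", []):
        a, b = labels[ent["i"]], labels[ent["j"]]
        intra[a, b] = intra[b, a] = float(ent["value"])
    inter = np.zeros((n, n))
    for ent in doc.get("inter_coupling", []):
        a, b = labels[ent["i"]], labels[ent["j"]]
        inter[a, b] = inter[b, a] = float(ent["value"])
    return BiasParameters(topology, linear, intra, inter)
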