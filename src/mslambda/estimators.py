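"""Endstate analysis: λc binning, transitions, ΔG, and ΔΔG assembly.

A frame belongs to endstate (sequence) *m* when, at every site, the
substituent prescribed by *m* carries λ ≥ λc; otherwise it is unassigned.
With λc = 0.99 (the conventional cutoff) the assignment approaches the exact
endstate populations, and the free energy difference between two sequences is

    ΔG_m = −kT ln(P_m / P_ref) − (B_m − B_ref)

where P are assigned-frame fractions and B_m is the applied linear-bias
energy at vertex m.  Subtracting the applied bias makes the estimator valid
even when the landscape is only approximately flattened; the correction can
be switched off to mimic the perfectly-flattened assumption.  Uncertainties
are moving-block bootstrap standard errors; sequences never observed are
reported as unavailable (missing), never as ±infinity.

A *transition* is the entry of the trajectory into an endstate bin different
from the last-visited endstate; unassigned gaps are transparent, so a brief
excursion out of a bin and back does not count.  Transition counts are the
convergence currency of λ-dynamics: free energies are only as good as the
number of independent endstate visits behind them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alchemical_core import KB, AlchemicalTopology, ValidationError
from .alf import BiasParameters
from .sampler import LambdaTrajectory

__all__ = [
    "EndstateSeries",
    "TransitionCounts",
    "FreeEnergyEstimate",
    "DDGResult",
    "assign_endstates",
    "count_transitions",
    "free_energy_from_populations",
    "ddg_cycle",
    "multi_mutant_report",
]


@dataclass
class EndstateSeries:
    """Per-frame endstate assignment of one trajectory."""

    topology: AlchemicalTopology
    labels: np.ndarray  # (n_frames,) object array: sequence label or None
    selections: np.ndarray  # (n_frames, n_sites) argmax substituent indices
    lambda_c: float
    model_time: float  # total model time spanned (model units)

    @property
    def n_frames(self) -> int:
        return int(self.labels.shape[0])

    @property
    def n_assigned(self) -> int:
        return int(sum(1 for x in self.labels if x is not None))

    def visits(self) -> list[tuple[str, int]]:
        """Run-length encoding of assigned visits (gaps collapsed)."""
        out: list[tuple[str, int]] = []
        for lab in self.labels:
            if lab is None:
                continue
            if out and out[-1][0] == lab:
                out[-1] = (lab, out[-1][1] + 1)
            else:
                out.append((lab, 1))
        return out


def assign_endstates(
    traj: LambdaTrajectory, lambda_c: float = 0.99
) -> EndstateSeries:
    """Bin every frame of a λ trajectory into endstates at cutoff λc."""
    if not 0.5 < lambda_c < 1.0:
        raise ValidationError("lambda_c must lie in (0.5, 1)")
    topo = traj.topology
    n_frames = traj.n_frames
    sel = np.empty((n_frames, topo.n_sites), dtype=np.int64)
    ok = np.ones(n_frames, dtype=bool)
    for s in range(topo.n_sites):
        block = traj.frames[:, topo.site_slice(s)]
        sel[:, s] = np.argmax(block, axis=1)
        ok &= np.max(block, axis=1) >= lambda_c
    labels = np.empty(n_frames, dtype=object)
    labels[:] = None
    for f in np.nonzero(ok)[0]:
        labels[f] = topo.sequence_of(sel[f])
    return EndstateSeries(
        topology=topo,
        labels=labels,
        selections=sel,
        lambda_c=lambda_c,
        model_time=traj.model_time,
    )


@dataclass
class TransitionCounts:
    """Per-sequence transition counts and rates (model-time units)."""

    counts: dict[str, int]
    total: int
    model_time: float
    rates: dict[str, float]  # counts per unit model time

    def count(self, seq: str) -> int:
        return self.counts.get(seq, 0)


def count_transitions(
    series: EndstateSeries | Sequence[EndstateSeries],
) -> TransitionCounts:
    """Count entries into each endstate from a different previously visited one.

    The first visit of a trajectory is not a transition.  When several series
    are given (replicas), counts are summed; visit history never crosses a
    replica boundary.
    """
    series_list = [series] if isinstance(series, EndstateSeries) else list(series)
    if not series_list:
        raise ValidationError("count_transitions needs at least one series")
    counts: dict[str, int] = {}
    time = 0.0
    for ser in series_list:
        time += ser.model_time
        prev: str | None = None
        for lab, _ in ser.visits():
            if prev is not None and lab != prev:
                counts[lab] = counts.get(lab, 0) + 1
            prev = lab
    total = sum(counts.values())
    rates = {k: (v / time if time > 0 else math.nan) for k, v in counts.items()}
    return TransitionCounts(counts=counts, total=total, model_time=time, rates=rates)


@dataclass
class FreeEnergyEstimate:
    """Per-sequence ΔG relative to a reference, with bootstrap SEs."""

    reference: str
    sequences: tuple[str, ...]
    dg: dict[str, float]  # NaN where unavailable
    se: dict[str, float]
    counts: dict[str, int]
    n_frames: int
    lambda_c: float
    temperature: float
    bias_corrected: bool

    def available(self, seq: str) -> bool:
        return math.isfinite(self.dg.get(seq, math.nan))


def _vertex_bias_energies(
    topology: AlchemicalTopology, bias: BiasParameters | None
) -> dict[str, float]:
    out: dict[str, float] = {}
    for sel in topology.iter_vertices():
        seq = topology.sequence_of(sel)
        out[seq] = 0.0 if bias is None else bias.vertex_linear_energy(sel)
    return out


def free_energy_from_populations(
    series: EndstateSeries | Sequence[EndstateSeries],
    bias: BiasParameters | None = None,
    temperature: float = 298.0,
    n_boot: int = 50,
    rng: np.random.Generator | None = None,
    reference: str | None = None,
    bias_correction: bool = True,
    sequences: Sequence[str] | None = None,
) -> FreeEnergyEstimate:
    """Population-ratio free energies ΔG_m = −kT ln(P_m/P_ref) − (B_m − B_ref).

    ``sequences`` restricts the report (default: every sequence in the
    topology's map, e.g. only matched states when desired).  The reference
    defaults to the all-reference vertex (the native sequence by
    construction) and must have been observed at least once.
    """
    series_list = [series] if isinstance(series, EndstateSeries) else list(series)
    if not series_list:
        raise ValidationError("free_energy_from_populations needs >= 1 series")
    topo = series_list[0].topology
    labels = np.concatenate([s.labels for s in series_list])
    n_frames = labels.shape[0]
    kT = KB * temperature
    rng = np.random.default_rng(0) if rng is None else rng

    if reference is None:
        reference = topo.sequence_of((0,) * topo.n_sites)
    if sequences is None:
        seqs = tuple(dict.fromkeys(topo.sequence_map.values()))
    else:
        seqs = tuple(sequences)
    if reference not in seqs:
        seqs = (reference,) + seqs
    bvert = _vertex_bias_energies(topo, bias if bias_correction else None)

    def estimate(labs: np.ndarray) -> dict[str, float]:
        cnt: dict[str, int] = {}
        for lab in labs:
            if lab is not None:
                cnt[lab] = cnt.get(lab, 0) + 1
        nref = cnt.get(reference, 0)
        out = {}
        for seq in seqs:
            nm = cnt.get(seq, 0)
            if nm == 0 or nref == 0:
                out[seq] = math.nan
            else:
                out[seq] = -kT * math.log(nm / nref) - (
                    bvert[seq] - bvert[reference]
                )
        return out

    counts: dict[str, int] = {seq: 0 for seq in seqs}
    for lab in labels:
        if lab in counts:
            counts[lab] += 1
    if counts[reference] == 0:
        raise ValidationError(
            f"reference sequence {reference!r} was never observed"
        )
    dg = estimate(labels)

    block = max(1, n_frames // 20)
    n_blocks = max(1, n_frames // block)
    boot_vals: dict[str, list[float]] = {seq: [] for seq in seqs}
    for _ in range(n_boot):
        starts = rng.integers(0, max(1, n_frames - block + 1), size=n_blocks)
        idx = (starts[:, None] + np.arange(block)[None, :]).ravel()[:n_frames]
        est = estimate(labels[idx])
        for seq in seqs:
            if math.isfinite(est[seq]):
                boot_vals[seq].append(est[seq])
    se = {}
    for seq in seqs:
        vals = boot_vals[seq]
        if math.isfinite(dg[seq]) and len(vals) >= 2:
            se[seq] = float(np.std(vals))
        elif seq == reference:
            se[seq] = 0.0
        else:
            se[seq] = math.nan

    return FreeEnergyEstimate(
        reference=reference,
        sequences=seqs,
        dg=dg,
        se=se,
        counts=counts,
        n_frames=n_frames,
        lambda_c=series_list[0].lambda_c,
        temperature=temperature,
        bias_corrected=bias_correction and bias is not None,
    )


@dataclass
class DDGResult:
    """Thermodynamic-cycle ΔΔG_b = ΔG_bound − ΔG_unbound per mutant."""

    reference: str
    sequences: tuple[str, ...]
    ddg: dict[str, float]
    se: dict[str, float]
    bound: FreeEnergyEstimate
    unbound: FreeEnergyEstimate

    def available(self, seq: str) -> bool:
        return math.isfinite(self.ddg.get(seq, math.nan))


def ddg_cycle(bound: FreeEnergyEstimate, unbound: FreeEnergyEstimate) -> DDGResult:
    """Close the thermodynamic cycle: per mutant, ΔΔG_b = ΔG_bound − ΔG_unbound.

    Standard errors combine in quadrature; a leg that is unavailable makes
    the mutant's ΔΔG unavailable.
    """
    if set(bound.sequences) != set(unbound.sequences):
        raise ValidationError("bound and unbound legs cover different sequences")
    if bound.reference != unbound.reference:
        raise ValidationError("bound and unbound legs use different references")
    ddg = {}
    se = {}
    for seq in bound.sequences:
        ddg[seq] = bound.dg[seq] - unbound.dg[seq]
        se[seq] = math.sqrt(bound.se[seq] ** 2 + unbound.se[seq] ** 2) if (
            math.isfinite(bound.se[seq]) and math.isfinite(unbound.se[seq])
        ) else math.nan
    return DDGResult(
        reference=bound.reference,
        sequences=bound.sequences,
        ddg=ddg,
        se=se,
        bound=bound,
        unbound=unbound,
    )


def multi_mutant_report(
    result: DDGResult,
    topology: AlchemicalTopology,
    transitions: Mapping[str, TransitionCounts] | TransitionCounts | None = None,
) -> pd.DataFrame:
    """Ranked multi-mutant table: one row per sequence, sorted by ΔΔG.

    Intermediate single-position mutants present in multi-site topologies
    appear automatically because every vertex sequence is a row.  Unavailable
    values sort last and stay missing (NaN) in the table.
    """
    rows = []
    if isinstance(transitions, TransitionCounts):
        transitions = {"": transitions}
    for seq in result.sequences:
        row = {
            "sequence": seq,
            "ddg": result.ddg.get(seq, math.nan),
            "se": result.se.get(seq, math.nan),
            "n_frames_bound": result.bound.counts.get(seq, 0),
            "n_frames_unbound": result.unbound.counts.get(seq, 0),
        }
        if transitions is not None:
            for name, tc in transitions.items():
                col = f"transitions_{name}" if name else "transitions"
                row[col] = tc.count(seq)
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values("ddg", na_position="last", kind="mergesort").reset_index(
        drop=True
    )
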