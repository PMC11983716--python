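"""DNA base-pair perturbation schemes.

Mutating a DNA site means mutating the complementary base on the opposite
strand too.  Three strategies for wiring the λ variables are supported:

* ``one_lambda_per_pair`` (1λ): a single λ drives each base-pair
  transformation; substituents are whole Watson–Crick pairs, so mispaired
  states cannot occur.
* ``two_lambda`` (2λ): each strand's base gets its own λ; each variant
  position contributes two Watson–Crick *paired* sites, and vertex states may
  be mispaired (noncanonical).
* ``coupled_two_lambda`` (coupled 2λ): as 2λ, plus a quadratic inter-site
  coupling bias Ψ between the paired sites' λ variables, subject to the
  convention Ψ_{s1,tj} = Ψ_{si,t1} = 0 (reference rows/columns vanish).

The Ψ tensor generated here carries −Ψ₀ on complementary (matched)
non-reference substituent pairs.  Destabilizing the concerted double mutation
by Ψ₀ is, up to per-site linear terms that the flattening bias absorbs,
equivalent to stabilizing the mispaired intermediates: it cancels pairwise
cooperativity between the two strands' λ variables, decoupling their
transitions so single-strand flips are no longer blocked by the mispair
penalty.  (With the reference rows pinned to zero, this gauge is the only one
available to express that decoupling.)

Sequences are reported in the primary-strand convention; complement-strand
substituent labels are stored explicitly on the complement sites, but
sequence labels use the primary strand, with mispaired vertices marked
explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alchemical_core import AlchemicalTopology, Site, ValidationError
from .alf import BiasParameters

__all__ = [
    "COMPLEMENT",
    "SCHEMES",
    "MutationSpec",
    "SchemeBuild",
    "build_scheme",
    "matched_state_filter",
    "variant_positions",
]

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

SCHEMES = ("one_lambda_per_pair", "two_lambda", "coupled_two_lambda")

#: short CLI aliases for the three schemes
SCHEME_ALIASES = {
    "1l": "one_lambda_per_pair",
    "2l": "two_lambda",
    "coupled2l": "coupled_two_lambda",
}


def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValidationError(f"invalid bases {sorted(bad)} in sequence {seq!r}")
    return seq


@dataclass(frozen=True)
class MutationSpec:
    """A native sequence, its mutants, and the λ-wiring scheme."""

    native: str
    mutants: tuple[str, ...]
    scheme: str = "one_lambda_per_pair"
    psi0: float = 2.0  # coupling strength of the coupled 2λ scheme, kcal/mol

    def __post_init__(self) -> None:
        object.__setattr__(self, "native", _check_sequence(self.native))
        muts = tuple(_check_sequence(m) for m in (
            [self.mutants] if isinstance(self.mutants, str) else self.mutants
        ))
        object.__setattr__(self, "mutants", muts)
        if not muts:
            raise ValidationError("at least one mutant sequence is required")
        for m in muts:
            if len(m) != len(self.native):
                raise ValidationError(
                    f"mutant {m!r} length differs from native {self.native!r}"
                )
        if all(m == self.native for m in muts):
            raise ValidationError("at least one position must differ from native")
        scheme = SCHEME_ALIASES.get(self.scheme, self.scheme)
        if scheme not in SCHEMES:
            raise ValidationError(f"unknown scheme {self.scheme!r}")
        object.__setattr__(self, "scheme", scheme)


def variant_positions(spec: MutationSpec) -> list[int]:
    """0-based positions at which any mutant differs from the native sequence."""
    return [
        p
        for p in range(len(spec.native))
        if any(m[p] != spec.native[p] for m in spec.mutants)
    ]


@dataclass
class SchemeBuild:
    """Topology plus the scheme's structural bias (Ψ for the coupled scheme)."""

    topology: AlchemicalTopology
    initial_bias: BiasParameters
    spec: MutationSpec
    positions: list[int]


def _position_bases(spec: MutationSpec, pos: int) -> list[str]:
    """Primary-strand base choices at a variant position, native first."""
    bases = [spec.native[pos]]
    for m in spec.mutants:
        if m[pos] not in bases:
            bases.append(m[pos])
    return bases


def build_scheme(spec: MutationSpec) -> SchemeBuild:
    """Construct the alchemical topology realizing a perturbation scheme.

    The sequence map enumerates all vertex combinations.  For the 2λ schemes
    a vertex whose paired sites carry non-complementary bases is labeled
    ``primary|complement`` (complement read as its strand's bases), so
    mispaired combinations are distinguishable from physical sequences.
    """
    positions = variant_positions(spec)
    native = spec.native

    if spec.scheme == "one_lambda_per_pair":
        sites = [
            Site(
                f"bp{p + 1}",
                tuple(f"{b}" for b in _position_bases(spec, p)),
            )
            for p in positions
        ]
        topo_tmp = AlchemicalTopology(sites)
        seq_map = {}
        for sel in topo_tmp.iter_vertices():
            s = list(native)
            for k, p in enumerate(positions):
                s[p] = _position_bases(spec, p)[sel[k]]
            seq_map[sel] = "".join(s)
        topology = AlchemicalTopology(sites, sequence_map=seq_map)
        return SchemeBuild(topology, BiasParameters.zeros(topology), spec, positions)

    # 2λ schemes: two paired sites per variant position, one per strand
    sites = []
    pairing: dict[int, int] = {}
    per_pos_bases = []
    for p in positions:
        bases = _position_bases(spec, p)
        per_pos_bases.append(bases)
        a = len(sites)
        sites.append(Site(f"bp{p + 1}:fwd", tuple(bases)))
        sites.append(Site(f"bp{p + 1}:rev", tuple(COMPLEMENT[b] for b in bases)))
        pairing[a] = a + 1
        pairing[a + 1] = a

    topo_tmp = AlchemicalTopology(sites, pairing=pairing)
    seq_map = {}
    for sel in topo_tmp.iter_vertices():
        primary = list(native)
        comp = []
        matched = True
        for k, p in enumerate(positions):
            i_fwd, i_rev = sel[2 * k], sel[2 * k + 1]
            b_fwd = per_pos_bases[k][i_fwd]
            b_rev = COMPLEMENT[per_pos_bases[k][i_rev]]  # rev site's own base
            primary[p] = b_fwd
            comp.append(COMPLEMENT[b_rev])  # what the rev strand implies fwd
            if i_fwd != i_rev:
                matched = False
        label = "".join(primary)
        if not matched:
            label = label + "|" + "".join(comp)
        seq_map[sel] = label
    topology = AlchemicalTopology(sites, pairing=pairing, sequence_map=seq_map)

    bias = BiasParameters.zeros(topology)
    if spec.scheme == "coupled_two_lambda":
        psi = np.zeros((topology.n_coords, topology.n_coords))
        for k in range(len(positions)):
            s_fwd, s_rev = 2 * k, 2 * k + 1
            n = topology.sites[s_fwd].n
            for i in range(1, n):  # reference rows/columns stay zero
                a = topology.coord_index(s_fwd, i)
                b = topology.coord_index(s_rev, i)  # same index <=> complementary
                psi[a, b] = psi[b, a] = -spec.psi0
        bias = BiasParameters(topology, inter_coupling=psi)
    return SchemeBuild(topology, bias, spec, positions)


def matched_state_filter(topology: AlchemicalTopology) -> list[tuple[int, ...]]:
    """Vertex selections whose paired sites carry complementary bases.

    For 1λ topologies (no pairing) every vertex is a physical sequence.
    """
    matched = []
    for sel in topology.iter_vertices():
        ok = True
        for a, b in topology.pairing.items():
            if a < b:
                base_a = topology.sites[a].substituents[sel[a]]
                base_b = topology.sites[b].substituents[sel[b]]
                if COMPLEMENT[base_a] != base_b:
                    ok = False
                    break
        if ok:
            matched.append(sel)
    return matched
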