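"""Seed-set detection via SCC condensation.

The seed set of a metabolic network is the minimal set of compounds the
network cannot synthesize internally — operationally, the members of the
strongly connected components (SCCs) that have no incoming edge in the SCC
condensation. Each seed compound carries a confidence

    C = 1 / |SCC|

reflecting that within a source SCC any single member suffices as the
exogenous entry point. Compounds with C below a threshold (default 0.2,
i.e. source SCCs larger than 5 nodes) are discarded whole-SCC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import networkx as nx

from .errors import ValidationError
from .model_io import MetabolicNetwork

__all__ = ["SeedSet", "condense_sccs", "detect_seed_set"]


@dataclass
class SeedSet:
    """Seed metabolites of one model with per-compound confidence.

    ``members`` maps metabolite id → confidence C ∈ (0, 1] as an exact
    rational; ``scc_of`` maps every *network* node to its SCC index.
    """

    model_id: str
    members: dict[str, Fraction] = field(default_factory=dict)
    scc_of: dict[str, int] = field(default_factory=dict)

    def __contains__(self, metabolite: str) -> bool:
        return metabolite in self.members

    def __len__(self) -> int:
        return len(self.members)

    def total_confidence(self) -> Fraction:
        return sum(self.members.values(), Fraction(0))


def condense_sccs(
    net: MetabolicNetwork,
) -> tuple[dict[str, int], set[tuple[int, int]]]:
    """Partition nodes into SCCs and build the condensation DAG.

    Returns ``(scc_of, condensation_edges)`` where ``scc_of`` assigns each
    node an SCC index and the edges link SCC indices. Indices are assigned
    deterministically (by the sorted smallest member of each component) so
    output never depends on node iteration order.
    """
    g = net.to_networkx()
    comps = sorted(
        (sorted(c) for c in nx.strongly_connected_components(g)),
        key=lambda c: c[0],
    )
    scc_of = {node: i for i, comp in enumerate(comps) for node in comp}
    cond_edges = {
        (scc_of[u], scc_of[v]) for u, v in net.edges if scc_of[u] != scc_of[v]
    }
    return scc_of, cond_edges


def detect_seed_set(
    net: MetabolicNetwork, threshold: float | Fraction = Fraction(1, 5)
) -> SeedSet:
    """Detect the seed set: members of source SCCs, thresholded on C.

    Parameters
    ----------
    net
        The directed metabolite graph.
    threshold
        Minimum confidence C = 1/|SCC| for a compound to be retained;
        must lie in (0, 1]. The default 0.2 keeps source SCCs of ≤ 5 nodes.
        Thresholding is all-or-none per SCC since C is constant within one.
    """
    threshold = Fraction(threshold).limit_denominator(10**9)
    if not (0 < threshold <= 1):
        raise ValidationError(f"threshold must be in (0, 1], got {threshold}")

    scc_of, cond_edges = condense_sccs(net)
    has_incoming = {j for _, j in cond_edges}

    sizes: dict[int, int] = {}
    for node, idx in scc_of.items():
        sizes[idx] = sizes.get(idx, 0) + 1

    members: dict[str, Fraction] = {}
    for node, idx in scc_of.items():
        if idx in has_incoming:
            continue
        conf = Fraction(1, sizes[idx])
        if conf >= threshold:
            members[node] = conf
    return SeedSet(model_id=net.model_id, members=members, scc_of=scc_of)
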