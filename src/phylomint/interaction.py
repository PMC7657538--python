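"""Pairwise metabolic competition and complementarity indices.

Both indices are directional, computed for an ordered species pair (A, B)
from seed sets and network membership:

* competition(A, B) — the confidence-weighted fraction of A's seed set that
  is also in B's seed set: Σ C_A(m) over SeedSet_A ∩ SeedSet_B, divided by
  Σ C_A(m) over SeedSet_A. Measures nutritional overlap.

* complementarity(A, B) — the fraction of A's seeds that occur in B's
  network as *non*-seeds: |SeedSet_A ∩ (nodes(B) \\ SeedSet_B)| divided by
  |SeedSet_A ∩ nodes(B)|. Measures A's potential to consume what B can
  produce. When no seed of A occurs anywhere in B's network the index is
  defined as 0 (no shared namespace, no measurable complementarity).

Indices are returned as exact rationals (`fractions.Fraction`); convert
with `float()` where needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

from .errors import ConfigurationError, UndefinedIndexError
from .model_io import MetabolicNetwork
from .seedset import SeedSet

__all__ = [
    "InteractionRecord",
    "competition_index",
    "complementarity_index",
    "all_pairs",
]


@dataclass(frozen=True)
class InteractionRecord:
    """One ordered species pair with both indices.

    ``shared_namespace`` is False when no seed of the source occurs in the
    target's network (the complementarity denominator was zero).
    """

    source_id: str
    target_id: str
    competition: float
    complementarity: float
    seed_size_source: int
    seed_size_target: int
    shared_namespace: bool


def competition_index(seed_a: SeedSet, seed_b: SeedSet) -> Fraction:
    """Metabolic competition index of A toward B (confidence-weighted)."""
    if not seed_a.members:
        raise UndefinedIndexError(
            f"seed set of {seed_a.model_id!r} is empty; competition undefined"
        )
    shared = sum(
        (c for m, c in seed_a.members.items() if m in seed_b.members), Fraction(0)
    )
    return shared / seed_a.total_confidence()


def complementarity_index(
    seed_a: SeedSet, net_b: MetabolicNetwork, seed_b: SeedSet
) -> Fraction:
    """Metabolic complementarity index of A toward B (unweighted counts)."""
    if not seed_a.members:
        raise UndefinedIndexError(
            f"seed set of {seed_a.model_id!r} is empty; complementarity undefined"
        )
    in_b = {m for m in seed_a.members if m in net_b.nodes}
    if not in_b:
        return Fraction(0)
    non_seed_of_b = {m for m in in_b if m not in seed_b.members}
    return Fraction(len(non_seed_of_b), len(in_b))


def all_pairs(
    models: Sequence[tuple[MetabolicNetwork, SeedSet]]
) -> list[InteractionRecord]:
    """Compute both indices for every ordered pair of distinct models.

    Returns n·(n−1) records in deterministic (source, target) id order.
    """
    ids = [net.model_id for net, _ in models]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ConfigurationError(f"duplicate model ids: {dupes}")
    indexed = sorted(models, key=lambda pair: pair[0].model_id)
    records: list[InteractionRecord] = []
    for net_a, seed_a in indexed:
        for net_b, seed_b in indexed:
            if net_a.model_id == net_b.model_id:
                continue
            comp = competition_index(seed_a, seed_b)
            in_b = any(m in net_b.nodes for m in seed_a.members)
            cmpl = complementarity_index(seed_a, net_b, seed_b)
            records.append(
                InteractionRecord(
                    source_id=net_a.model_id,
                    target_id=net_b.model_id,
                    competition=float(comp),
                    complementarity=float(cmpl),
                    seed_size_source=len(seed_a),
                    seed_size_target=len(seed_b),
                    shared_namespace=in_b,
                )
            )
    return records
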