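"""Phylogenetic normalization: binned Z-scores and Tukey outlier flags.

Raw interaction indices covary with phylogenetic distance (close relatives
share seed compounds). To decouple them, ordered species pairs are binned
by patristic distance in fixed-width intervals (default 0.01), small bins
are merged upward into their closest qualifying predecessor (the first
bin's size is the minimum-size reference), and each index is Z-scored
within its bin. Pairs beyond |Z| = 2.698 — Tukey's 1.5×IQR fences under
normality — are flagged as outliers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

from .errors import ValidationError

__all__ = [
    "BinAssignment",
    "ZRecord",
    "ZTable",
    "TUKEY_Z",
    "assign_bins",
    "merge_small_bins",
    "zscores_within_bins",
    "flag_outliers",
]

#: Z-score equivalent of Tukey's 1.5×IQR outlier fences under normality
TUKEY_Z = 2.698

PairKey = tuple[str, str]
Flag = Literal["high", "low", "none"]


@dataclass
class BinAssignment:
    """Assignment of ordered pairs to phylogenetic-distance bins."""

    width: float
    bin_of_pair: dict[PairKey, int] = field(default_factory=dict)

    @property
    def bin_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for b in self.bin_of_pair.values():
            sizes[b] = sizes.get(b, 0) + 1
        return sizes


@dataclass(frozen=True)
class ZRecord:
    source: str
    target: str
    metric: str
    raw: float
    bin_index: int
    z: float
    outlier_flag: Flag = "none"


@dataclass
class ZTable:
    records: list[ZRecord] = field(default_factory=list)

    def by_metric(self, metric: str) -> list[ZRecord]:
        return [r for r in self.records if r.metric == metric]


def assign_bins(
    distances: Mapping[PairKey, float], width: float = 0.01
) -> BinAssignment:
    """Bin each pair into the half-open interval [k·width, (k+1)·width).

    A distance exactly on a boundary lands in the upper bin.
    """
    if width <= 0:
        raise ValidationError(f"bin width must be positive, got {width}")
    out = BinAssignment(width=width)
    for pair, d in distances.items():
        if d < 0:
            raise ValidationError(f"negative distance {d} for pair {pair}")
        out.bin_of_pair[pair] = int(math.floor(d / width))
    return out


def merge_small_bins(
    bins: BinAssignment, minimum: int | None = None
) -> BinAssignment:
    """Merge undersized bins upward into their closest qualifying predecessor.

    The minimum size defaults to the size of the lowest-distance bin
    *before* any merging (the reference-bin convention). Scanning bins in
    increasing-distance order, a bin smaller than the minimum is merged
    into the closest preceding bin whose current size meets the minimum; a
    leading run with no qualifying predecessor merges forward into the
    first subsequent bin that qualifies. The result conserves the total
    pair count and leaves no bin below the minimum unless only one bin
    remains.
    """
    sizes = bins.bin_sizes
    if not sizes:
        raise ValidationError("cannot merge an empty bin assignment")
    order = sorted(sizes)
    if minimum is None:
        minimum = sizes[order[0]]

    current = dict(sizes)
    target: dict[int, int] = {b: b for b in order}  # bin -> merged destination
    pending: list[int] = []  # leading bins with no qualifying predecessor
    last_ok: int | None = None
    for b in order:
        if current[b] >= minimum:
            dest = b
        elif last_ok is not None:
            dest = last_ok
        else:
            pending.append(b)
            continue
        if dest != b:
            current[dest] += current.pop(b)
            target[b] = dest
        for p in pending:  # forward-merge fallback for a leading short run
            current[dest] += current.pop(p)
            target[p] = dest
        pending.clear()
        if current[dest] >= minimum:
            last_ok = dest
    if pending:  # everything was undersized: collapse into the first bin
        dest = order[0]
        for p in pending:
            if p != dest:
                current[dest] = current.get(dest, 0) + current.pop(p)
                target[p] = dest

    merged = BinAssignment(width=bins.width)
    for pair, b in bins.bin_of_pair.items():
        merged.bin_of_pair[pair] = target[b]
    return merged


def _sample_std(values: Sequence[float], mean: float) -> float:
    n = len(values)
    if n < 2:
        return 0.0
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))


def zscores_within_bins(
    values: Mapping[PairKey, float],
    bins: BinAssignment,
    metric: str,
    ddof: int = 1,
) -> ZTable:
    """Z-score a metric within each bin (sample sd, n−1 by default).

    Singleton and zero-variance bins yield z = 0 for their members: no
    outlier is detectable there.
    """
    missing = [p for p in values if p not in bins.bin_of_pair]
    if missing:
        raise ValidationError(f"pairs without a bin: {sorted(missing)[:5]}")

    grouped: dict[int, list[PairKey]] = {}
    for pair in values:
        grouped.setdefault(bins.bin_of_pair[pair], []).append(pair)

    table = ZTable()
    for b in sorted(grouped):
        pairs = sorted(grouped[b])
        xs = [values[p] for p in pairs]
        mean = sum(xs) / len(xs)
        if max(xs) == min(xs):  # constant bin: no spread regardless of fp error
            sd = 0.0
        elif ddof == 1:
            sd = _sample_std(xs, mean)
        else:
            sd = math.sqrt(sum((v - mean) ** 2 for v in xs) / len(xs))
        for pair, x in zip(pairs, xs):
            z = (x - mean) / sd if sd > 0 else 0.0
            table.records.append(
                ZRecord(pair[0], pair[1], metric, x, b, z)
            )
    return table


def flag_outliers(
    table: ZTable, high: float = TUKEY_Z, low: float = -TUKEY_Z
) -> ZTable:
    """Flag records with z strictly above ``high`` or strictly below ``low``."""
    if not high > low:
        raise ValidationError(f"high threshold must exceed low ({high} vs {low})")
    flagged = ZTable()
    for r in table.records:
        flag: Flag = "high" if r.z > high else ("low" if r.z < low else "none")
        flagged.records.append(
            ZRecord(r.source, r.target, r.metric, r.raw, r.bin_index, r.z, flag)
        )
    return flagged
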