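"""Patristic distances from a user-supplied Newick tree.

The phylogenetic distance between two species is the sum of branch lengths
on the unique tree path between their leaves. Trees are consumed, never
inferred: build one externally (e.g. marker-gene alignment + FastTree) with
leaf labels matching the model ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy

from .errors import InputFormatError, ValidationError

__all__ = ["DistanceTable", "read_newick", "patristic_distances", "write_distances"]


@dataclass
class DistanceTable:
    """Symmetric pairwise patristic distances keyed by unordered label pair."""

    pairs: dict[frozenset[str], float] = field(default_factory=dict)

    def distance(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        return self.pairs[frozenset((a, b))]

    def labels(self) -> set[str]:
        out: set[str] = set()
        for pair in self.pairs:
            out.update(pair)
        return out


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree, enforcing branch lengths and unique leaf labels.

    Raises
    ------
    InputFormatError
        On unparsable input, a missing branch length on any non-root edge,
        or duplicate leaf labels.
    """
    path = Path(path)
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise InputFormatError(f"cannot parse Newick file {path}: {exc}") from exc

    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise InputFormatError(f"duplicate leaf labels in {path}: {dupes}")

    root = tree.seed_node
    for edge in tree.preorder_edge_iter():
        if edge.head_node is root:
            continue
        if edge.length is None:
            head = edge.head_node
            name = head.taxon.label if head.taxon else "<internal>"
            raise InputFormatError(
                f"missing branch length on edge above {name!r} in {path}"
            )
    return tree


def patristic_distances(
    tree: dendropy.Tree, labels: Iterable[str] | None = None
) -> DistanceTable:
    """Sum of branch lengths between every unordered pair of leaves.

    Parameters
    ----------
    tree
        A tree as returned by :func:`read_newick`.
    labels
        Restrict to these leaf labels (default: all leaves).

    Raises
    ------
    ValidationError
        If a requested label is not a leaf of the tree.
    """
    leaf_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    wanted = set(labels) if labels is not None else leaf_labels
    missing = sorted(wanted - leaf_labels)
    if missing:
        raise ValidationError(f"labels not found in tree: {missing}")

    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in wanted}
    out = DistanceTable()
    ordered = sorted(wanted)
    for i, la in enumerate(ordered):
        for lb in ordered[i + 1 :]:
            d = pdm.patristic_distance(taxa[la], taxa[lb])
            out.pairs[frozenset((la, lb))] = float(d)
    return out


def write_distances(table: DistanceTable, path: str | Path) -> None:
    """Write long-format TSV: label_a, label_b, distance (sorted pairs)."""
    rows = sorted((tuple(sorted(pair)), d) for pair, d in table.pairs.items())
    with open(path, "w") as fh:
        fh.write("label_a\tlabel_b\tdistance\n")
        for (a, b), d in rows:
            fh.write(f"{a}\t{b}\t{d:.6g}\n")
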