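"""Directed cooperation network from outlier Z-scores, plus Infomap I/O.

An edge A→B is added when the pair's complementarity Z-score is
significantly high (default > 2.698) and its competition Z-score is low
(default < −1.000, a deliberately relaxed fence so that strongly
complementary pairs are kept while still constraining competition). The
graph is exported as a zero-based link list for Infomap community
detection; Infomap itself runs externally.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx

from .errors import InputFormatError, ValidationError
from .normalize import TUKEY_Z, ZTable

__all__ = [
    "InteractionGraph",
    "build_graph",
    "export_infomap",
    "parse_infomap_modules",
    "run_infomap",
    "within_genus_proportions",
]

#: Infomap flags used for community detection on the cooperation network
INFOMAP_FLAGS = ("--directed", "--zero-based-numbering", "--num-trials", "10")


@dataclass
class InteractionGraph:
    """Directed species-level cooperation graph.

    Edge attributes carry the two Z-scores the edge was admitted on.
    """

    nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (u, v), attrs in self.edges.items():
            g.add_edge(u, v, **attrs)
        return g


def build_graph(
    z: ZTable,
    complement_threshold: float = TUKEY_Z,
    competition_threshold: float = -1.000,
    keep_isolated: bool = False,
) -> InteractionGraph:
    """Build the cooperation graph from a Z-table holding both metrics.

    An edge (A, B) exists iff z_complementarity(A, B) strictly exceeds
    ``complement_threshold`` AND z_competition(A, B) is strictly below
    ``competition_threshold``. Isolated nodes are dropped unless
    ``keep_isolated``.
    """
    z_comp: dict[tuple[str, str], float] = {}
    z_compete: dict[tuple[str, str], float] = {}
    for r in z.records:
        key = (r.source, r.target)
        if r.metric == "complementarity":
            z_comp[key] = r.z
        elif r.metric == "competition":
            z_compete[key] = r.z
    only_one = set(z_comp) ^ set(z_compete)
    if only_one:
        raise ValidationError(
            f"pairs with a single metric in Z-table: {sorted(only_one)[:5]}"
        )

    g = InteractionGraph()
    all_species = {s for s, _ in z_comp} | {t for _, t in z_comp}
    if keep_isolated:
        g.nodes.update(all_species)
    for key in sorted(z_comp):
        zc, zk = z_comp[key], z_compete[key]
        if zc > complement_threshold and zk < competition_threshold:
            g.nodes.update(key)
            g.edges[key] = {"z_complementarity": zc, "z_competition": zk}
    return g


def export_infomap(
    g: InteractionGraph, out_dir: str | Path, stem: str = "network"
) -> tuple[Path, Path]:
    """Write the Infomap link-list input and the integer↔id mapping TSV.

    Nodes get contiguous zero-based integer ids in sorted-label order.
    Returns ``(link_list_path, mapping_path)``.
    """
    if not g.nodes:
        raise ValidationError("cannot export an empty graph")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ordered = sorted(g.nodes)
    idx = {label: i for i, label in enumerate(ordered)}

    link_path = out_dir / f"{stem}.links"
    with open(link_path, "w") as fh:
        for u, v in sorted(g.edges):
            fh.write(f"{idx[u]} {idx[v]}\n")

    map_path = out_dir / f"{stem}.idmap.tsv"
    with open(map_path, "w") as fh:
        fh.write("node_id\tmodel_id\n")
        for label in ordered:
            fh.write(f"{idx[label]}\t{label}\n")
    return link_path, map_path


def read_id_mapping(mapping: str | Path) -> dict[int, str]:
    out: dict[int, str] = {}
    with open(mapping) as fh:
        header = fh.readline()
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputFormatError(f"{mapping}:{lineno}: bad mapping line")
            out[int(parts[0])] = parts[1]
    return out


def parse_infomap_modules(
    tree_output: str | Path, mapping: str | Path
) -> dict[str, str]:
    """Parse Infomap ``.tree`` output into model id → hierarchical module path.

    Lines look like ``1:1:2 0.0231 "name" 4`` — module path, flow, quoted
    name, zero-based node id. Comment lines start with ``#``.
    """
    idmap = read_id_mapping(mapping)
    modules: dict[str, str] = {}
    with open(tree_output) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise InputFormatError(f"{tree_output}:{lineno}: bad tree line")
            path = parts[0]
            node_id = int(parts[-1])
            if node_id not in idmap:
                raise InputFormatError(
                    f"{tree_output}:{lineno}: node id {node_id} not in mapping"
                )
            # strip the leaf rank: "1:1:2" -> module "1:1"
            module = path.rsplit(":", 1)[0] if ":" in path else path
            modules[idmap[node_id]] = module
    return modules


def run_infomap(
    link_list: str | Path, out_dir: str | Path, infomap_bin: str = "Infomap"
) -> Path:
    """Invoke a local Infomap installation on an exported link list.

    Returns the path of the ``.tree`` output. Requires Infomap on PATH;
    raises ``ValidationError`` if it is not found.
    """
    if shutil.which(infomap_bin) is None:
        raise ValidationError(f"Infomap binary {infomap_bin!r} not found on PATH")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subprocess.run(
        [infomap_bin, str(link_list), str(out_dir), *INFOMAP_FLAGS, "--tree"],
        check=True,
    )
    return out_dir / (Path(link_list).stem + ".tree")


def within_genus_proportions(
    significant_pairs: set[tuple[str, str]],
    taxonomy: Mapping[str, str],
) -> dict[str, tuple[int, int, float]]:
    """Per-genus proportion of significantly cooperative ordered pairs.

    For each genus with ≥ 2 annotated members: the number of same-genus
    ordered pairs n(n−1), how many of those are in ``significant_pairs``,
    and their ratio. Genera with a single member are excluded.
    """
    by_genus: dict[str, list[str]] = {}
    for model_id, genus in taxonomy.items():
        by_genus.setdefault(genus, []).append(model_id)

    out: dict[str, tuple[int, int, float]] = {}
    for genus, members in sorted(by_genus.items()):
        if len(members) < 2:
            continue
        n_pairs = len(members) * (len(members) - 1)
        n_sig = sum(
            1
            for a in members
            for b in members
            if a != b and (a, b) in significant_pairs
        )
        out[genus] = (n_pairs, n_sig, n_sig / n_pairs)
    return out


def write_graph_tsv(g: InteractionGraph, path: str | Path) -> None:
    """Edge-list TSV with the Z-scores each edge was admitted on."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tz_complementarity\tz_competition\n")
        for (u, v) in sorted(g.edges):
            attrs = g.edges[(u, v)]
            fh.write(
                f"{u}\t{v}\t{attrs['z_complementarity']:.6g}"
                f"\t{attrs['z_competition']:.6g}\n"
            )


def write_graphml(g: InteractionGraph, path: str | Path) -> None:
    nx.write_graphml(g.to_networkx(), str(path))
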