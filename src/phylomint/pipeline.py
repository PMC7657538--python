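"""End-to-end orchestration: models + tree in, Z-table and network out.

Stages run in a fixed order — graphs → seeds → indices → distances → bins
→ Z-scores → flags → network — and every output TSV is written with fixed
column order, a header line and 6-significant-digit floats so reruns are
byte-identical. A JSON manifest records input hashes, all parameters and
per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigurationError
from .interaction import all_pairs
from .model_io import (
    GraphOptions,
    MetabolicNetwork,
    project_to_metabolite_graph,
    read_edge_list_with_isolates,
    read_sbml,
)
from .netbuild import InteractionGraph, build_graph, export_infomap, write_graph_tsv
from .normalize import (
    TUKEY_Z,
    assign_bins,
    flag_outliers,
    merge_small_bins,
    zscores_within_bins,
)
from .phylo import patristic_distances, read_newick, write_distances
from .seedset import detect_seed_set

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    model_dir: str | Path
    tree_path: str | Path
    output_dir: str | Path
    seed_threshold: float = 0.2
    bin_width: float = 0.01
    z_high: float = TUKEY_Z
    z_low_competition: float = -1.000
    rng_seed: int = 0
    graph_options: GraphOptions = field(default_factory=GraphOptions)
    quiet: bool = False


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _log(cfg: RunConfig, msg: str) -> None:
    if not cfg.quiet:
        print(f"[phylomint] {msg}", file=sys.stderr)


def _load_models(cfg: RunConfig) -> list[MetabolicNetwork]:
    model_dir = Path(cfg.model_dir)
    nets: list[MetabolicNetwork] = []
    for path in sorted(model_dir.iterdir()):
        if path.suffix in {".xml", ".sbml"}:
            rxns = read_sbml(path, cfg.graph_options)
            nets.append(project_to_metabolite_graph(rxns, cfg.graph_options))
        elif path.suffix in {".tsv", ".txt", ".edges"}:
            nets.append(read_edge_list_with_isolates(path))
    if len(nets) < 2:
        raise ConfigurationError(
            f"need at least 2 models in {model_dir}, found {len(nets)}"
        )
    ids = [n.model_id for n in nets]
    if len(set(ids)) != len(ids):
        raise ConfigurationError(f"duplicate model ids: {sorted(ids)}")
    return nets


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full pipeline; returns the manifest (also written to JSON).

    Pre-flight validation (model/tree label match) happens before any
    output is written, so configuration errors never leave partial files.
    """
    t0 = time.monotonic()
    out_dir = Path(cfg.output_dir)

    # ---- pre-flight ----
    nets = _load_models(cfg)
    tree = read_newick(cfg.tree_path)
    leaf_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = sorted({n.model_id for n in nets} - leaf_labels)
    if missing:
        raise ConfigurationError(f"model ids missing from tree: {missing}")

    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "inputs": {
            "model_dir": str(cfg.model_dir),
            "tree": {"path": str(cfg.tree_path), "sha256": _sha256(Path(cfg.tree_path))},
            "models": {
                n.model_id: len(n.nodes) for n in nets
            },
        },
        "parameters": {
            "seed_threshold": cfg.seed_threshold,
            "bin_width": cfg.bin_width,
            "z_high": cfg.z_high,
            "z_low_competition": cfg.z_low_competition,
            "rng_seed": cfg.rng_seed,
        },
        "stages": {},
        "outputs": {},
    }

    # ---- seeds & indices ----
    _log(cfg, f"seed detection on {len(nets)} models")
    seeds = [detect_seed_set(n, cfg.seed_threshold) for n in nets]
    records = all_pairs(list(zip(nets, seeds)))
    idx_path = out_dir / "indices.tsv"
    with open(idx_path, "w") as fh:
        fh.write(
            "source\ttarget\tcompetition\tcomplementarity"
            "\tseedA_size\tseedB_size\tshared_namespace_flag\n"
        )
        for r in records:
            fh.write(
                f"{r.source_id}\t{r.target_id}\t{r.competition:.6g}"
                f"\t{r.complementarity:.6g}\t{r.seed_size_source}"
                f"\t{r.seed_size_target}\t{int(r.shared_namespace)}\n"
            )
    manifest["stages"]["indices"] = len(records)
    manifest["outputs"]["indices"] = str(idx_path)

    # ---- distances ----
    _log(cfg, "patristic distances")
    table = patristic_distances(tree, [n.model_id for n in nets])
    dist_path = out_dir / "dist.tsv"
    write_distances(table, dist_path)
    manifest["stages"]["distances"] = len(table.pairs)
    manifest["outputs"]["dist"] = str(dist_path)

    # ---- binning + Z + flags ----
    _log(cfg, "binned Z-scores")
    pair_dist = {
        (r.source_id, r.target_id): table.distance(r.source_id, r.target_id)
        for r in records
    }
    bins = merge_small_bins(assign_bins(pair_dist, cfg.bin_width))
    ztables = {}
    for metric, getter in (
        ("complementarity", lambda r: r.complementarity),
        ("competition", lambda r: r.competition),
    ):
        vals = {(r.source_id, r.target_id): getter(r) for r in records}
        zt = flag_outliers(
            zscores_within_bins(vals, bins, metric), cfg.z_high, -cfg.z_high
        )
        ztables[metric] = {(r.source, r.target): r for r in zt.records}

    z_path = out_dir / "ztable.tsv"
    from .normalize import ZTable

    combined = ZTable()
    with open(z_path, "w") as fh:
        fh.write(
            "source\ttarget\tcompetition\tcomplementarity\tdistance\tbin"
            "\tz_competition\tz_complementarity"
            "\tflag_competition\tflag_complementarity\n"
        )
        for r in records:
            key = (r.source_id, r.target_id)
            zc = ztables["complementarity"][key]
            zk = ztables["competition"][key]
            combined.records.append(zc)
            combined.records.append(zk)
            fh.write(
                f"{r.source_id}\t{r.target_id}\t{r.competition:.6g}"
                f"\t{r.complementarity:.6g}\t{pair_dist[key]:.6g}\t{zc.bin_index}"
                f"\t{zk.z:.6g}\t{zc.z:.6g}\t{zk.outlier_flag}\t{zc.outlier_flag}\n"
            )
    manifest["stages"]["ztable_rows"] = len(combined.records)
    manifest["outputs"]["ztable"] = str(z_path)

    # ---- network ----
    _log(cfg, "cooperation network")
    graph = build_graph(combined, cfg.z_high, cfg.z_low_competition)
    net_path = out_dir / "network.tsv"
    write_graph_tsv(graph, net_path)
    manifest["stages"]["network_edges"] = len(graph.edges)
    manifest["outputs"]["network"] = str(net_path)
    if graph.nodes:
        links, idmap = export_infomap(graph, out_dir)
        manifest["outputs"]["infomap_links"] = str(links)
        manifest["outputs"]["infomap_idmap"] = str(idmap)

    manifest["elapsed_s"] = round(time.monotonic() - t0, 3)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest["outputs"]["manifest"] = str(manifest_path)
    _log(cfg, f"done in {manifest['elapsed_s']}s")
    return manifest
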