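"""Synthetic inputs: the canonical toy network pair and random generators.

Everything downstream is testable without external genome data. The toy
pair is the worked example used to illustrate the indices: network A has
seed set {A, F, G, H} with F,G,H forming a 3-cycle SCC, network B has seed
set {F, I, J, K} with I,J a 2-cycle SCC; A and F are the only seeds of A
present in B's network, and A is a non-seed there, which pins the
competition index A→B at 1/6 and the complementarity index at 1/2.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Sequence

from .errors import ValidationError
from .model_io import MetabolicNetwork, Reaction, ReactionSet, write_edge_list

__all__ = [
    "SyntheticSpec",
    "toy_networks_fig6",
    "toy_networks_alternative",
    "random_models",
    "random_digraph",
    "random_tree",
    "write_demo",
]


def toy_networks_fig6() -> tuple[MetabolicNetwork, MetabolicNetwork]:
    """The canonical toy network pair of the worked example.

    Returns ``(netA, netB)`` with
    netA: A→B, F→G→H→F (3-cycle), H→B;
    netB: F→A, I⇄J (2-cycle), J→L, K→L.
    """
    net_a = MetabolicNetwork(model_id="toyA")
    for u, v in [("A", "B"), ("F", "G"), ("G", "H"), ("H", "F"), ("H", "B")]:
        net_a.add_edge(u, v)
    net_b = MetabolicNetwork(model_id="toyB")
    for u, v in [("F", "A"), ("I", "J"), ("J", "I"), ("K", "L"), ("J", "L")]:
        net_b.add_edge(u, v)
    return net_a, net_b


def toy_networks_alternative() -> tuple[MetabolicNetwork, MetabolicNetwork]:
    """A second, topologically different instantiation of the same constraints.

    Any pair of networks satisfying the worked example's stated seed
    memberships and shared-metabolite relations yields the same indices;
    this variant adds extra internal nodes and rewires non-seed structure.
    """
    net_a = MetabolicNetwork(model_id="toyA")
    # same seeds {A, F, G, H}; extra internal node C downstream
    for u, v in [("A", "C"), ("C", "B"), ("F", "G"), ("G", "H"), ("H", "F"),
                 ("F", "B")]:
        net_a.add_edge(u, v)
    net_b = MetabolicNetwork(model_id="toyB")
    # same seeds {F, I, J, K}; A reachable from K instead of F; extra sink M
    for u, v in [("K", "A"), ("F", "M"), ("I", "J"), ("J", "I"), ("J", "L"),
                 ("A", "L")]:
        net_b.add_edge(u, v)
    return net_a, net_b


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters for a random model collection with planted ground truth."""

    n_metabolites: int = 20
    n_reactions: int = 15
    reversible_fraction: float = 0.2
    rng_seed: int = 0
    planted_source_sccs: tuple[int, ...] = (1,)

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.planted_source_sccs):
            raise ValidationError("planted SCC sizes must be >= 1")
        if sum(self.planted_source_sccs) > self.n_metabolites:
            raise ValidationError(
                "planted SCC nodes exceed n_metabolites "
                f"({sum(self.planted_source_sccs)} > {self.n_metabolites})"
            )


def random_models(
    spec: SyntheticSpec, n_models: int = 1
) -> list[tuple[ReactionSet, dict[str, Fraction]]]:
    """Generate random reaction sets whose graphs contain planted source SCCs.

    Each model comes with its ground truth: the planted seed compounds and
    their confidences C = 1/|planted SCC|. Planted SCC nodes receive no
    incoming reactions from outside their cycle, so they are guaranteed
    source-SCC members of the projected graph (other, unplanted source
    SCCs may also arise among the free metabolites).
    """
    rng = random.Random(spec.rng_seed)
    out: list[tuple[ReactionSet, dict[str, Fraction]]] = []
    for k in range(n_models):
        model_id = f"syn{k}"
        mets = [f"m{i}_{model_id}" for i in range(spec.n_metabolites)]
        planted: list[list[str]] = []
        cursor = 0
        for size in spec.planted_source_sccs:
            planted.append(mets[cursor : cursor + size])
            cursor += size
        protected = {m for grp in planted for m in grp}
        free = mets[cursor:]

        reactions: list[Reaction] = []
        rid = 0
        # cycle reactions realize each planted SCC
        for grp in planted:
            if len(grp) == 1:
                continue
            for i, m in enumerate(grp):
                reactions.append(
                    Reaction(f"r{rid}", frozenset({m}),
                             frozenset({grp[(i + 1) % len(grp)]}), False, False)
                )
                rid += 1
        # planted nodes feed one free node each, so they are never isolated
        for grp in planted:
            if free:
                reactions.append(
                    Reaction(f"r{rid}", frozenset({grp[0]}),
                             frozenset({rng.choice(free)}), False, False)
                )
                rid += 1
        # random reactions among free metabolites only (never into protected)
        for _ in range(spec.n_reactions):
            if len(free) < 2:
                break
            n_sub = rng.randint(1, min(2, len(free)))
            n_prod = rng.randint(1, min(2, len(free)))
            subs = frozenset(rng.sample(free, n_sub))
            prods = frozenset(rng.sample(free, n_prod))
            rev = rng.random() < spec.reversible_fraction
            reactions.append(Reaction(f"r{rid}", subs, prods, rev, False))
            rid += 1

        truth = {
            m: Fraction(1, len(grp)) for grp in planted for m in grp
        }
        out.append((ReactionSet(model_id=model_id, reactions=reactions), truth))
    return out


def random_digraph(
    n_nodes: int, n_edges: int, rng_seed: int, model_id: str = "rand"
) -> MetabolicNetwork:
    """Uniform random simple digraph (no self-loops) for oracle testing."""
    rng = random.Random(rng_seed)
    nodes = [f"n{i}" for i in range(n_nodes)]
    net = MetabolicNetwork(model_id=model_id)
    net.nodes.update(nodes)
    for _ in range(n_edges):
        u, v = rng.sample(nodes, 2)
        net.add_edge(u, v)
    return net


def random_tree(labels: Sequence[str], rng_seed: int = 0) -> str:
    """Random bifurcating Newick string with positive branch lengths.

    Built by repeatedly joining two random subtrees; byte-identical for a
    fixed seed.
    """
    if len(labels) < 2:
        raise ValidationError("need at least 2 labels for a tree")
    rng = random.Random(rng_seed)
    subtrees = [str(l) for l in sorted(labels)]
    while len(subtrees) > 1:
        i, j = sorted(rng.sample(range(len(subtrees)), 2), reverse=True)
        a, b = subtrees.pop(i), subtrees.pop(j)
        la, lb = (round(rng.uniform(0.01, 1.0), 4) for _ in range(2))
        subtrees.append(f"({a}:{la},{b}:{lb})")
    return subtrees[0] + ";"


def write_demo(out_dir: str | Path, n_extra_models: int = 0, rng_seed: int = 0) -> dict:
    """Write toy networks (under ``models/``), a demo tree and a taxonomy.

    Enables a full end-to-end pipeline run with no external data. Returns a
    manifest of the written paths, including ``models_dir``.
    """
    out_dir = Path(out_dir)
    models_dir = out_dir / "models"
    models_dir.mkdir(parents=True, exist_ok=True)
    net_a, net_b = toy_networks_fig6()
    nets = [net_a, net_b]
    if n_extra_models:
        from .model_io import GraphOptions, project_to_metabolite_graph

        spec = SyntheticSpec(rng_seed=rng_seed, planted_source_sccs=(1, 3))
        opts = GraphOptions(strip_compartments=False)
        for rxns, _ in random_models(spec, n_models=n_extra_models):
            net = project_to_metabolite_graph(rxns, opts)
            # demo models share one metabolite namespace: drop the per-model tag
            renamed = MetabolicNetwork(model_id=net.model_id)
            renamed.nodes = {n.split("_")[0] for n in net.nodes}
            for u, v in net.edges:
                renamed.add_edge(u.split("_")[0], v.split("_")[0])
            nets.append(renamed)

    paths = {}
    for net in nets:
        p = models_dir / f"{net.model_id}.tsv"
        write_edge_list(net, p)
        paths[net.model_id] = str(p)
    tree_path = out_dir / "demo.nwk"
    tree_path.write_text(random_tree([n.model_id for n in nets], rng_seed) + "\n")
    tax_path = out_dir / "taxonomy.tsv"
    with open(tax_path, "w") as fh:
        fh.write("model_id\tgenus\n")
        for net in nets:
            fh.write(f"{net.model_id}\tDemo\n")
    return {
        "models_dir": str(models_dir),
        "networks": paths,
        "tree": str(tree_path),
        "taxonomy": str(tax_path),
    }
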