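"""Read metabolic models and project them onto directed metabolite graphs.

A genome-scale metabolic reconstruction (GENRE) is a set of reactions; the
reverse-ecology machinery downstream operates on a *metabolite graph*: a
directed graph whose nodes are metabolites and whose edges run from each
substrate of a reaction to each of its products (both directions for a
reversible reaction). Exchange/boundary reactions and the biomass objective
are excluded by default because they would turn every exchanged metabolite
into an artifactual source or sink.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import networkx as nx

from .errors import EmptyModelError, InputFormatError

__all__ = [
    "GraphOptions",
    "Reaction",
    "ReactionSet",
    "MetabolicNetwork",
    "read_sbml",
    "read_edge_list",
    "write_edge_list",
    "write_graphml",
    "project_to_metabolite_graph",
    "network_stats",
]

#: compartment tags commonly appended to metabolite ids (BiGG style: glc__D_c)
DEFAULT_COMPARTMENT_TAGS = frozenset(
    {"c", "e", "p", "m", "x", "r", "v", "n", "g", "h", "u", "l", "i", "c0", "e0", "p0"}
)

#: reaction-id prefixes that mark exchange / demand / sink pseudo-reactions
DEFAULT_BOUNDARY_PREFIXES = ("EX_", "DM_", "SK_", "R_EX_", "R_DM_", "R_SK_")

_BIOMASS_RE = re.compile(r"biomass|growth", re.IGNORECASE)


@dataclass(frozen=True)
class GraphOptions:
    """Options controlling model reading and graph projection.

    Parameters
    ----------
    drop_boundary
        Exclude exchange/demand/sink reactions (identified by boundary
        species, a one-sided stoichiometry, or a reaction-id prefix).
    drop_biomass
        Exclude reactions whose id or name matches ``biomass``/``growth``.
    strip_compartments
        Remove a trailing compartment tag (``_c``, ``_e``, ...) from
        metabolite ids so namespaces align across models.
    compartment_tags
        The set of suffixes treated as compartment tags.
    boundary_prefixes
        Reaction-id prefixes flagged as boundary.
    exclude_metabolites
        User-supplied metabolite ids (post-normalization) dropped from the
        graph, e.g. a currency-metabolite blacklist. Empty by default.
    """

    drop_boundary: bool = True
    drop_biomass: bool = True
    strip_compartments: bool = True
    compartment_tags: frozenset[str] = DEFAULT_COMPARTMENT_TAGS
    boundary_prefixes: tuple[str, ...] = DEFAULT_BOUNDARY_PREFIXES
    exclude_metabolites: frozenset[str] = frozenset()

    def normalize(self, met_id: str) -> str:
        """Normalize one metabolite id (strip SBML ``M_`` prefix, compartment tag)."""
        if met_id.startswith("M_"):
            met_id = met_id[2:]
        if self.strip_compartments:
            stem, sep, tail = met_id.rpartition("_")
            if sep and stem and tail in self.compartment_tags:
                met_id = stem
        return met_id


class Reaction(NamedTuple):
    reaction_id: str
    substrates: frozenset[str]
    products: frozenset[str]
    reversible: bool
    is_boundary: bool


@dataclass
class ReactionSet:
    """A parsed metabolic model: reactions with participant metabolite sets."""

    model_id: str
    reactions: list[Reaction] = field(default_factory=list)

    def non_boundary(self) -> list[Reaction]:
        return [r for r in self.reactions if not r.is_boundary]


@dataclass
class MetabolicNetwork:
    """Directed metabolite graph of one model.

    ``edges`` are ordered (substrate, product) pairs; self-loops are never
    stored. Every edge endpoint is a node, but isolated metabolites may be
    nodes without edges.
    """

    model_id: str
    nodes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            return
        self.nodes.add(u)
        self.nodes.add(v)
        self.edges.add((u, v))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

def read_sbml(path: str | Path, options: GraphOptions | None = None) -> ReactionSet:
    """Parse an SBML (Level 2/3) model into a :class:`ReactionSet`.

    Boundary reactions are flagged (not removed) so the projection step can
    decide; the biomass reaction is excluded here when
    ``options.drop_biomass`` is set, since it is not a chemical conversion.

    Raises
    ------
    InputFormatError
        If the file cannot be parsed as SBML.
    EmptyModelError
        If the model holds zero (usable) reactions.
    """
    import libsbml

    options = options or GraphOptions()
    path = Path(path)
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getModel() is None or doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise InputFormatError(f"cannot parse SBML file: {path}")
    model = doc.getModel()

    boundary_species = {
        sp.getId()
        for sp in model.getListOfSpecies()
        if sp.getBoundaryCondition()
    }

    reactions: list[Reaction] = []
    seen_ids: set[str] = set()
    for rxn in model.getListOfReactions():
        rid = rxn.getId()
        if rid in seen_ids:
            raise InputFormatError(f"duplicate reaction id {rid!r} in {path}")
        seen_ids.add(rid)
        if options.drop_biomass and (
            _BIOMASS_RE.search(rid) or _BIOMASS_RE.search(rxn.getName() or "")
        ):
            continue
        subs = frozenset(
            s.getSpecies() for s in rxn.getListOfReactants()
        )
        prods = frozenset(
            s.getSpecies() for s in rxn.getListOfProducts()
        )
        is_boundary = (
            rid.startswith(options.boundary_prefixes)
            or not subs
            or not prods
            or bool((subs | prods) & boundary_species)
        )
        subs_n = frozenset(options.normalize(m) for m in subs)
        prods_n = frozenset(options.normalize(m) for m in prods)
        reactions.append(
            Reaction(rid, subs_n, prods_n, bool(rxn.getReversible()), is_boundary)
        )

    if not reactions:
        raise EmptyModelError(f"model {path} contains no reactions")
    return ReactionSet(model_id=model.getId() or path.stem, reactions=reactions)


# ---------------------------------------------------------------------------
# Edge-list dialect
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path, model_id: str | None = None) -> MetabolicNetwork:
    """Read the plain ``source target`` edge-list dialect.

    Lines are whitespace-separated; ``#`` starts a comment line; blank lines
    are ignored. Duplicate edges collapse (set semantics).
    """
    path = Path(path)
    net = MetabolicNetwork(model_id=model_id or path.stem)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise InputFormatError(
                    f"{path}:{lineno}: expected 'source target', got {raw.rstrip()!r}"
                )
            net.add_edge(parts[0], parts[1])
    return net


def write_edge_list(net: MetabolicNetwork, path: str | Path) -> None:
    """Write a network in the edge-list dialect (sorted, hence deterministic).

    Isolated nodes are preserved as ``# node <id>`` comment lines so a
    round trip reproduces the node set exactly.
    """
    with open(path, "w") as fh:
        fh.write(f"# model {net.model_id}\n")
        connected = {u for u, _ in net.edges} | {v for _, v in net.edges}
        for node in sorted(net.nodes - connected):
            fh.write(f"# node {node}\n")
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")


def read_edge_list_with_isolates(path: str | Path) -> MetabolicNetwork:
    """Read an edge list, honouring ``# node`` comment lines written by
    :func:`write_edge_list`."""
    path = Path(path)
    net = read_edge_list(path)
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("# node "):
                net.nodes.add(line.split(maxsplit=2)[2])
            elif line.startswith("# model "):
                net.model_id = line.split(maxsplit=2)[2]
    return net


def write_graphml(net: MetabolicNetwork, path: str | Path) -> None:
    nx.write_graphml(net.to_networkx(), str(path))


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------

def project_to_metabolite_graph(
    rxns: ReactionSet, options: GraphOptions | None = None
) -> MetabolicNetwork:
    """Project a reaction set onto the directed metabolite graph.

    Every non-boundary reaction contributes a substrate→product edge for
    each (substrate, product) pair; reversible reactions also contribute
    the product→substrate edges. Self-loops (a metabolite on both sides)
    are dropped; they carry no reachability information.
    """
    options = options or GraphOptions()
    net = MetabolicNetwork(model_id=rxns.model_id)
    excl = options.exclude_metabolites
    pool = rxns.non_boundary() if options.drop_boundary else rxns.reactions
    for rxn in pool:
        subs = [m for m in rxn.substrates if m not in excl]
        prods = [m for m in rxn.products if m not in excl]
        net.nodes.update(subs)
        net.nodes.update(prods)
        for s in subs:
            for p in prods:
                net.add_edge(s, p)
                if rxn.reversible:
                    net.add_edge(p, s)
    return net


def network_stats(net: MetabolicNetwork) -> tuple[int, int, int, int]:
    """Return ``(n_nodes, n_edges, n_sources, n_sinks)``.

    A source is a node with in-degree 0, a sink one with out-degree 0;
    isolated nodes count as both.
    """
    has_in = {v for _, v in net.edges}
    has_out = {u for u, _ in net.edges}
    n_sources = sum(1 for n in net.nodes if n not in has_in)
    n_sinks = sum(1 for n in net.nodes if n not in has_out)
    return (len(net.nodes), len(net.edges), n_sources, n_sinks)
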