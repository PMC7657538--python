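"""Model reading and metabolite-graph projection."""

import pytest

from phylomint import (
    EmptyModelError,
    GraphOptions,
    InputFormatError,
    MetabolicNetwork,
    Reaction,
    ReactionSet,
    network_stats,
    project_to_metabolite_graph,
    read_edge_list,
    read_sbml,
    write_edge_list,
)
from phylomint.model_io import read_edge_list_with_isolates
from phylomint.fixtures import random_models, SyntheticSpec, toy_networks_fig6

from conftest import make_sbml


class TestReadSbml:
    def test_five_reactions_one_exchange(self, five_reaction_sbml):
        rxns = read_sbml(five_reaction_sbml)
        assert len(rxns.reactions) == 5
        assert len(rxns.non_boundary()) == 4
        boundary = [r for r in rxns.reactions if r.is_boundary]
        assert [r.reaction_id for r in boundary] == ["EX_a_e"]

    def test_single_irreversible_reaction(self, tmp_path):
        path = tmp_path / "one.xml"
        path.write_text(make_sbml("one", [("S", False), ("P", False)],
                                  [("R1", ["S"], ["P"], False)]))
        rxns = read_sbml(path)
        (rxn,) = rxns.reactions
        assert rxn.substrates == {"S"} and rxn.products == {"P"}
        assert not rxn.reversible

    def test_zero_reactions_is_empty_model(self, tmp_path):
        path = tmp_path / "empty.xml"
        path.write_text(make_sbml("empty", [("S", False)], []))
        with pytest.raises(EmptyModelError):
            read_sbml(path)

    def test_garbage_file_is_format_error(self, tmp_path):
        path = tmp_path / "junk.xml"
        path.write_text("this is not SBML")
        with pytest.raises(InputFormatError, match="junk.xml"):
            read_sbml(path)

    def test_biomass_reaction_dropped_by_default(self, tmp_path):
        path = tmp_path / "bm.xml"
        path.write_text(make_sbml(
            "bm", [("S", False), ("P", False)],
            [("R1", ["S"], ["P"], False),
             ("Growth_biomass", ["P"], ["S"], False)]))
        assert len(read_sbml(path).reactions) == 1
        keep = GraphOptions(drop_biomass=False)
        assert len(read_sbml(path, keep).reactions) == 2

    def test_boundary_species_flags_reaction(self, tmp_path):
        path = tmp_path / "bs.xml"
        path.write_text(make_sbml(
            "bs", [("S", True), ("P", False)],
            [("R1", ["S"], ["P"], False)]))
        assert read_sbml(path).reactions[0].is_boundary


class TestEdgeList:
    def test_two_lines(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A B\nB C\n")
        net = read_edge_list(p)
        assert net.nodes == {"A", "B", "C"}
        assert net.edges == {("A", "B"), ("B", "C")}

    def test_empty_file(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("")
        net = read_edge_list(p)
        assert net.nodes == set() and net.edges == set()

    def test_duplicate_lines_collapse(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A B\nA\tB\n")
        net = read_edge_list(p)
        assert len(net.nodes) == 2 and len(net.edges) == 1

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A B\nA B C\n")
        with pytest.raises(InputFormatError, match=":2"):
            read_edge_list(p)

    def test_round_trip_preserves_network(self, tmp_path, toy_pair):
        net_a, _ = toy_pair
        net_a.nodes.add("isolated")
        p = tmp_path / "rt.tsv"
        write_edge_list(net_a, p)
        again = read_edge_list_with_isolates(p)
        assert again == net_a
        assert again.model_id == net_a.model_id


class TestProjection:
    def test_irreversible_bipartite_expansion(self):
        rxns = ReactionSet("m", [Reaction("r", frozenset({"S1", "S2"}),
                                          frozenset({"P1"}), False, False)])
        net = project_to_metabolite_graph(rxns)
        assert net.edges == {("S1", "P1"), ("S2", "P1")}

    def test_reversible_adds_back_edges(self):
        rxns = ReactionSet("m", [Reaction("r", frozenset({"S"}),
                                          frozenset({"P"}), True, False)])
        net = project_to_metabolite_graph(rxns)
        assert net.edges == {("S", "P"), ("P", "S")}

    def test_compartment_stripping_merges_nodes(self):
        rxns = ReactionSet("m", [
            Reaction("r1", frozenset({"glc__D_c"}), frozenset({"pyr_c"}), False, False),
            Reaction("r2", frozenset({"glc__D_e"}), frozenset({"pyr_e"}), False, False),
        ])
        opts = GraphOptions(strip_compartments=True)
        # stripping happens at read time normally; emulate via normalize
        rxns = ReactionSet("m", [
            Reaction(r.reaction_id,
                     frozenset(opts.normalize(m) for m in r.substrates),
                     frozenset(opts.normalize(m) for m in r.products),
                     r.reversible, r.is_boundary)
            for r in rxns.reactions
        ])
        net = project_to_metabolite_graph(rxns, opts)
        assert net.nodes == {"glc__D", "pyr"}

    def test_strip_never_increases_node_count(self, five_reaction_sbml):
        stripped = project_to_metabolite_graph(
            read_sbml(five_reaction_sbml, GraphOptions(strip_compartments=True)))
        kept = project_to_metabolite_graph(
            read_sbml(five_reaction_sbml, GraphOptions(strip_compartments=False)),
            GraphOptions(strip_compartments=False))
        assert len(stripped.nodes) <= len(kept.nodes)

    def test_self_loops_dropped(self):
        rxns = ReactionSet("m", [Reaction("r", frozenset({"X", "Y"}),
                                          frozenset({"X"}), False, False)])
        net = project_to_metabolite_graph(rxns)
        assert ("X", "X") not in net.edges
        assert ("Y", "X") in net.edges

    @pytest.mark.parametrize("seed", range(10))
    def test_edge_count_matches_pair_enumeration(self, seed):
        """Projected edges equal the brute-force substrate x product pairs."""
        spec = SyntheticSpec(n_metabolites=12, n_reactions=10, rng_seed=seed,
                             reversible_fraction=0.3, planted_source_sccs=(2,))
        (rxns, _), = random_models(spec)
        net = project_to_metabolite_graph(rxns, GraphOptions(strip_compartments=False))
        expected = set()
        for r in rxns.non_boundary():
            for s in r.substrates:
                for p in r.products:
                    if s != p:
                        expected.add((s, p))
                        if r.reversible:
                            expected.add((p, s))
        assert net.edges == expected


class TestNetworkStats:
    def test_chain(self):
        net = MetabolicNetwork("m")
        net.add_edge("A", "B")
        net.add_edge("B", "C")
        assert network_stats(net) == (3, 2, 1, 1)

    def test_two_cycle_has_no_sources_or_sinks(self):
        net = MetabolicNetwork("m")
        net.add_edge("A", "B")
        net.add_edge("B", "A")
        assert network_stats(net) == (2, 2, 0, 0)

    def test_toy_network_a_single_source(self, toy_pair):
        net_a, _ = toy_pair
        n, e, n_sources, n_sinks = network_stats(net_a)
        # brute-force degree count: only A has in-degree 0 (F,G,H cycle feeds itself)
        in_deg = {node: 0 for node in net_a.nodes}
        for _, v in net_a.edges:
            in_deg[v] += 1
        assert n_sources == sum(1 for d in in_deg.values() if d == 0) == 1
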