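"""SBML I/O, compartment collapsing, compound graphs, lightest paths,
sub-network extraction and set algebra."""

import itertools
from math import inf

import networkx as nx
import numpy as np
import pytest

import fingernet as fn
from fingernet.network import (
    CompoundGraph,
    Metabolite,
    MetabolicNetwork,
    Reaction,
    build_compound_graph,
    export_subnetwork,
    extract_subnetwork,
    lightest_path,
    load_name_mapping,
    map_fingerprint_to_network,
    merge_compartments,
    read_sbml,
    subnetwork_algebra,
    write_sbml,
)
from tests.conftest import random_toy_graph


def simple_net(reactions, mets=None):
    if mets is None:
        ids = {m for r in reactions for m, _ in r.substrates + r.products}
        mets = [Metabolite(m, m, "c") for m in sorted(ids)]
    return MetabolicNetwork(mets, reactions, name="t")


def rxn(rid, subs, prods, rev=False):
    return Reaction(rid, rid, tuple((m, 1.0) for m in subs),
                    tuple((m, 1.0) for m in prods), rev)


class TestSBML:
    def test_round_trip_counts_and_attributes(self, tmp_path):
        net = fn.generate_toy_network(5, 7, n_compartments=2, seed=9)
        path = tmp_path / "toy.xml"
        write_sbml(net, path)
        back = read_sbml(path)
        assert back.n_metabolites == net.n_metabolites
        assert back.n_reactions == net.n_reactions
        assert {m.compartment for m in back.metabolites} == {
            m.compartment for m in net.metabolites
        }
        assert all(r.reversible for r in back.reactions)

    def test_minimal_model(self, tmp_path):
        net = simple_net([rxn("r1", ["a"], ["b"])])
        path = tmp_path / "mini.xml"
        write_sbml(net, path)
        back = read_sbml(path)
        assert (back.n_metabolites, back.n_reactions) == (2, 1)

    def test_truncated_file_is_atomic_error(self, tmp_path):
        net = simple_net([rxn("r1", ["a"], ["b"])])
        path = tmp_path / "full.xml"
        write_sbml(net, path)
        text = path.read_text()
        bad = tmp_path / "trunc.xml"
        bad.write_text(text[: len(text) // 2])
        with pytest.raises(ValueError, match="unparseable|no model"):
            read_sbml(bad)


class TestMergeCompartments:
    def test_transport_only_network_collapses_to_nothing(self):
        net = MetabolicNetwork(
            [Metabolite("glc_c", "glucose", "c"), Metabolite("glc_m", "glucose", "m")],
            [rxn("t1", ["glc_c"], ["glc_m"], rev=True)],
        )
        res = merge_compartments(net)
        assert res.network.n_metabolites == 1
        assert res.network.n_reactions == 0
        assert res.removed_transport == ("t1",)
        assert res.id_map == {"glc_c": "glc", "glc_m": "glc"}

    def test_duplicate_reactions_deduplicated(self):
        net = MetabolicNetwork(
            [
                Metabolite("glc_c", "g", "c"), Metabolite("g6p_c", "g", "c"),
                Metabolite("glc_m", "g", "m"), Metabolite("g6p_m", "g", "m"),
            ],
            [
                rxn("HEX_c", ["glc_c"], ["g6p_c"]),
                rxn("HEX_m", ["glc_m"], ["g6p_m"]),
            ],
        )
        res = merge_compartments(net)
        assert res.network.n_reactions == 1
        assert res.network.reactions[0].id == "HEX_c"
        assert res.deduplicated == {"HEX_c": ("HEX_m",)}

    def test_reversible_duplicates_merge_across_direction(self):
        net = MetabolicNetwork(
            [Metabolite("a_c", "a", "c"), Metabolite("b_c", "b", "c")],
            [rxn("r1", ["a_c"], ["b_c"], rev=True), rxn("r2", ["b_c"], ["a_c"], rev=True)],
        )
        assert merge_compartments(net).network.n_reactions == 1

    def test_idempotent(self):
        net = fn.generate_toy_network(6, 9, n_compartments=3, seed=5)
        once = merge_compartments(net).network
        twice = merge_compartments(once).network
        assert {m.id for m in twice.metabolites} == {m.id for m in once.metabolites}
        assert {r.id for r in twice.reactions} == {r.id for r in once.reactions}

    @pytest.mark.parametrize("seed", range(5))
    def test_collapse_bounds(self, seed):
        net = fn.generate_toy_network(5, 8, n_compartments=2, seed=seed)
        merged = merge_compartments(net).network
        assert merged.n_metabolites < net.n_metabolites  # shared across comps
        assert merged.n_reactions <= net.n_reactions


class TestCompoundGraph:
    def test_linear_chain_counts(self):
        net = simple_net([rxn("r1", ["A"], ["B"]), rxn("r2", ["B"], ["C"])])
        g = build_compound_graph(net)
        assert len(g.graph) == 5
        assert g.graph.number_of_edges() == 4

    def test_side_compound_removed_other_edges_kept(self):
        net = simple_net([rxn("r1", ["A", "h2o"], ["B"])])
        g = build_compound_graph(net, side_compounds=["h2o"])
        assert "h2o" not in g.graph
        assert set(g.graph.neighbors("r1")) == {"A", "B"}

    def test_reaction_losing_a_side_is_dropped(self):
        net = simple_net([rxn("r1", ["h2o"], ["B"]), rxn("r2", ["B"], ["C"])])
        g = build_compound_graph(net, side_compounds=["h2o"])
        assert "r1" not in g.graph and "r2" in g.graph

    def test_unknown_side_compound_warns(self):
        net = simple_net([rxn("r1", ["A"], ["B"])])
        with pytest.warns(UserWarning, match="not in network"):
            build_compound_graph(net, side_compounds=["nope"])

    def test_unit_scheme_weights(self):
        net = simple_net([rxn("r1", ["A"], ["B"]), rxn("r2", ["B"], ["C"])])
        g = build_compound_graph(net, weight_scheme="unit")
        assert all(g.node_weight(m) == 1.0 for m in g.metabolite_nodes)

    def test_degree_squared_weights(self):
        net = simple_net([rxn("r1", ["A"], ["B"]), rxn("r2", ["B"], ["C"])])
        g = build_compound_graph(net)
        assert g.node_weight("B") == 4.0
        assert g.node_weight("A") == 1.0


class TestLightestPath:
    def test_hub_detour_avoided(self, hub_graph):
        p = lightest_path(hub_graph, "A", "C")
        assert p.nodes == ("A", "r1", "B", "r2", "C")
        assert p.cost == 14.0  # 4+1+4+1+4; the hub route costs 4+1+64+1+4

    def test_unreachable_pair(self):
        net = simple_net([rxn("r1", ["A"], ["B"]), rxn("r2", ["C"], ["D"])])
        g = build_compound_graph(net)
        p = lightest_path(g, "A", "C")
        assert p.nodes == () and p.cost == inf

    def test_absent_node_errors(self, hub_graph):
        with pytest.raises(KeyError):
            lightest_path(hub_graph, "A", "nope")

    def test_same_endpoints_error(self, hub_graph):
        with pytest.raises(ValueError, match="differ"):
            lightest_path(hub_graph, "A", "A")

    def test_unit_weights_equal_bfs(self):
        rng = np.random.default_rng(77)
        for _ in range(15):
            g = random_toy_graph(rng, weight_scheme="unit")
            mets = sorted(g.metabolite_nodes)
            src, dst = mets[0], mets[-1]
            p = lightest_path(g, src, dst)
            expect = nx.shortest_path_length(g.graph, src, dst) + 1
            assert len(p.nodes) == expect

    @pytest.mark.parametrize("scheme", ["unit", "degree", "degree_squared"])
    def test_oracle_equivalence_exhaustive(self, scheme):
        """Lightest path equals the minimum over exhaustive simple-path
        enumeration on random graphs of <= 12 nodes."""
        rng = np.random.default_rng(123)
        for _ in range(20):
            g = random_toy_graph(rng, weight_scheme=scheme)
            mets = sorted(g.metabolite_nodes)
            for src, dst in itertools.combinations(mets[:4], 2):
                got = lightest_path(g, src, dst)
                best = min(
                    (
                        (sum(g.node_weight(n) for n in path), tuple(path))
                        for path in nx.all_simple_paths(g.graph, src, dst)
                    ),
                    default=(inf, ()),
                )
                assert (got.cost, got.nodes) == best


class TestSubnetworks:
    def test_two_seed_chain(self):
        net = simple_net([rxn("r1", ["A"], ["B"]), rxn("r2", ["B"], ["C"])])
        g = build_compound_graph(net)
        sn = extract_subnetwork(g, {"A", "C"})
        assert sn.metabolites == {"A", "B", "C"}
        assert sn.reactions == {"r1", "r2"}
        assert sn.provenance[("A", "C")] == ("A", "r1", "B", "r2", "C")

    def test_adjacent_seeds(self):
        net = simple_net([rxn("r1", ["A"], ["B"]), rxn("r2", ["B"], ["C"])])
        g = build_compound_graph(net)
        sn = extract_subnetwork(g, {"A", "B"})
        assert sn.metabolites == {"A", "B"} and sn.reactions == {"r1"}

    def test_too_few_mappable_seeds(self, hub_graph):
        with pytest.raises(ValueError, match="not in graph.*'zzz'"):
            extract_subnetwork(hub_graph, {"A", "zzz"})

    def test_unreachable_pairs_recorded(self):
        net = simple_net([rxn("r1", ["A"], ["B"]), rxn("r2", ["C"], ["D"])])
        g = build_compound_graph(net)
        sn = extract_subnetwork(g, {"A", "B", "C"})
        assert ("A", "C") in sn.unreachable_pairs
        assert ("B", "C") in sn.unreachable_pairs

    def test_every_nonseed_node_on_a_recorded_path(self, hub_graph):
        sn = extract_subnetwork(hub_graph, {"A", "C", "X0"})
        on_paths = {n for path in sn.provenance.values() for n in path}
        assert sn.nodes == on_paths

    def test_seed_monotonicity(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            g = random_toy_graph(rng)
            mets = sorted(g.metabolite_nodes)
            if len(mets) < 4:
                continue
            small = extract_subnetwork(g, mets[:3])
            big = extract_subnetwork(g, mets[:4])
            assert small.metabolites <= big.metabolites
            assert small.reactions <= big.reactions


class TestAlgebra:
    @pytest.fixture()
    def pair(self, hub_graph):
        a = extract_subnetwork(hub_graph, {"A", "C"})
        b = extract_subnetwork(hub_graph, {"A", "B"})
        return a, b

    def test_self_difference_is_empty(self, pair):
        a, _ = pair
        d = subnetwork_algebra(a, a, "difference")
        assert d.is_empty() and d.seeds == frozenset()

    def test_difference_set_rule(self, pair):
        a, b = pair
        d = subnetwork_algebra(a, b, "difference")
        assert d.metabolites == a.metabolites - b.metabolites
        assert d.reactions == a.reactions - b.reactions

    def test_intersection_contained_in_both(self, pair):
        a, b = pair
        i = subnetwork_algebra(a, b, "intersect")
        assert i.metabolites <= a.metabolites and i.metabolites <= b.metabolites
        assert i.reactions <= a.reactions and i.reactions <= b.reactions

    def test_union_merges_provenance(self, pair):
        a, b = pair
        u = subnetwork_algebra(a, b, "union")
        assert set(u.provenance) >= set(a.provenance) | set(b.provenance)

    def test_different_parents_rejected(self, hub_graph):
        a = extract_subnetwork(hub_graph, {"A", "C"})
        net = simple_net([rxn("r1", ["A"], ["B"]), rxn("r2", ["B"], ["C"])])
        g2 = build_compound_graph(net)
        b = extract_subnetwork(g2, {"A", "C"})
        with pytest.raises(ValueError, match="different parent"):
            subnetwork_algebra(a, b, "intersect")


class TestMapping:
    def test_curated_hit(self):
        mapping = load_name_mapping()
        seeds, unmapped = map_fingerprint_to_network(["Succinate"], mapping)
        assert seeds == {"succ"} and unmapped == []

    def test_missing_name_reported(self):
        mapping = load_name_mapping()
        seeds, unmapped = map_fingerprint_to_network(
            ["Succinate", "Isopropanol"], mapping
        )
        assert unmapped == ["Isopropanol"]

    def test_case_insensitive(self):
        mapping = load_name_mapping()
        seeds, _ = map_fingerprint_to_network(["succinate", "GLYCINE"], mapping)
        assert seeds == {"succ", "gly"}

    def test_ambiguous_synonyms_rejected(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("name\tnetwork_id\nFoo\tid1\nfoo\tid2\n")
        with pytest.raises(ValueError, match="ambiguous"):
            load_name_mapping(p)

    def test_empty_mapping_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            map_fingerprint_to_network(["Succinate"], {})


class TestExport:
    @pytest.fixture()
    def small_subnet(self):
        net = simple_net([rxn("r1", ["A"], ["B"]), rxn("r2", ["B"], ["C"])])
        g = build_compound_graph(net)
        return extract_subnetwork(g, {"A", "B"})

    def test_sif_rows(self, small_subnet, tmp_path):
        p = tmp_path / "s.sif"
        export_subnetwork(small_subnet, p, "sif")
        rows = p.read_text().strip().splitlines()
        assert rows == ["r1\tinteracts\tA", "r1\tinteracts\tB"]

    def test_graphml_round_trip(self, small_subnet, tmp_path):
        p = tmp_path / "s.graphml"
        export_subnetwork(small_subnet, p, "graphml")
        g = nx.read_graphml(p)
        assert set(g.nodes) == small_subnet.nodes
        assert {tuple(sorted(e)) for e in g.edges} == {
            tuple(sorted(e)) for e in small_subnet.edges
        }

    def test_unknown_format(self, small_subnet, tmp_path):
        with pytest.raises(ValueError, match="unknown export format"):
            export_subnetwork(small_subnet, tmp_path / "x", "dot")

    def test_empty_subnetwork_rejected(self, small_subnet, tmp_path):
        empty = subnetwork_algebra(small_subnet, small_subnet, "difference")
        with pytest.raises(ValueError, match="empty"):
            export_subnetwork(empty, tmp_path / "x.sif", "sif")
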