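"""Graph construction, hub search, topology and enrichment against oracles."""

import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    bfs_distance,
    clustering_by_triangles,
    floyd_warshall,
    path_length_mean,
    union_find_components,
)
from tgfbsig.io import write_edges_tsv
from tgfbsig.network import (
    assign_layers,
    geneset_enrichment,
    induced_subnetwork,
    load_and_merge_edges,
    regulator_step_size,
    select_hubs,
    topology_metrics,
)


def _write(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path


class TestLoadAndMerge:
    def test_confidence_threshold_strict_at_500(self, tmp_path):
        p = _write(tmp_path / "e.tsv", ["protein1\tprotein2\tcombined_score",
                                        "A\tB\t500", "C\tD\t501"])
        g = load_and_merge_edges([p])
        assert not g.has_edge("A", "B")
        assert g.has_edge("C", "D")

    def test_duplicate_edge_keeps_highest_confidence(self, tmp_path):
        p = _write(tmp_path / "e.tsv", ["A\tB\t600", "B\tA\t700"])
        g = load_and_merge_edges([p])
        assert g.number_of_edges() == 1
        assert g.edges["A", "B"]["confidence"] == 700

    def test_curated_edges_exempt_from_threshold(self, tmp_path):
        p = _write(tmp_path / "cur.tsv", ["A\tB"])
        g = load_and_merge_edges([p])
        assert g.edges["A", "B"]["confidence"] == 1000
        assert g.edges["A", "B"]["provenance"] == "curated"

    def test_malformed_line_reports_number(self, tmp_path):
        p = _write(tmp_path / "e.tsv", ["A\tB\t900", "A\tB\tC\tD\t1"])
        with pytest.raises(ValueError, match=":2:"):
            load_and_merge_edges([p])

    def test_bad_confidence_reports_number(self, tmp_path):
        p = _write(tmp_path / "e.tsv", ["A\tB\tnot_a_number"])
        with pytest.raises(ValueError, match=":1:"):
            load_and_merge_edges([p])

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(12)
        g = nx.gnm_random_graph(30, 200, seed=12)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        for u, v in g.edges:
            g.edges[u, v]["confidence"] = int(rng.integers(501, 1001))
            g.edges[u, v]["provenance"] = "database"
        path = tmp_path / "rt.tsv"
        write_edges_tsv(g, path)
        g2 = load_and_merge_edges([path])
        assert ({frozenset(e) for e in g2.edges}
                == {frozenset(e) for e in g.edges})
        for u, v in g.edges:
            assert g2.edges[u, v]["confidence"] == g.edges[u, v]["confidence"]


def _random_graph(n, p, seed):
    g = nx.gnp_random_graph(n, p, seed=seed)
    return nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})


class TestInducedSubnetwork:
    def test_absent_seeds_all_unmapped(self):
        g = _random_graph(5, 0.5, 1)
        sub, report = induced_subnetwork(g, ["X", "Y"])
        assert sub.number_of_nodes() == 0
        assert report.unmapped == ["X", "Y"]

    def test_triangle_seed_set(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("A", "C"), ("C", "D")])
        sub, report = induced_subnetwork(g, ["A", "B", "C"])
        assert sub.number_of_edges() == 3
        assert report.n_components == 1
        assert report.isolated == []

    def test_empty_seed_list_rejected(self):
        with pytest.raises(ValueError):
            induced_subnetwork(nx.Graph([("A", "B")]), [])

    @pytest.mark.parametrize("seed", range(5))
    def test_components_match_union_find(self, seed):
        g = _random_graph(15, 0.15, seed)
        rng = np.random.default_rng(seed)
        seeds = list(rng.choice(sorted(g.nodes), size=8, replace=False))
        sub, report = induced_subnetwork(g, seeds)
        oracle = union_find_components(sub.nodes, sub.edges)
        assert report.components == oracle


class TestSelectHubs:
    def _graph(self):
        # S1..S4 seeds; H3 touches 3 seeds, H1 touches 1, ALB touches 4
        edges = [("H3", "S1"), ("H3", "S2"), ("H3", "S3"), ("H1", "S1"),
                 ("ALB", "S1"), ("ALB", "S2"), ("ALB", "S3"), ("ALB", "S4")]
        return nx.Graph(edges)

    def test_ranking_by_links(self):
        hubs, _ = select_hubs(self._graph(), ["S1", "S2", "S3", "S4"],
                              [["H3", "H1"]], n_per_pool=2, exclusion=())
        assert [(h.symbol, h.links_to_seed) for h in hubs] == [("H3", 3), ("H1", 1)]

    def test_exclusion_skip_recorded(self):
        hubs, skipped = select_hubs(self._graph(), ["S1", "S2", "S3", "S4"],
                                    [["ALB", "H3", "H1"]], n_per_pool=2)
        assert [h.symbol for h in hubs] == ["H3", "H1"]
        assert [(s.symbol, s.links_to_seed, s.excluded) for s in skipped] == [
            ("ALB", 4, True)]

    def test_input_order_invariance(self):
        g = _random_graph(15, 0.3, 3)
        seeds = sorted(g.nodes)[:5]
        pool = sorted(set(g.nodes) - set(seeds))
        a, _ = select_hubs(g, seeds, [pool], n_per_pool=3, exclusion=())
        b, _ = select_hubs(g, seeds, [list(reversed(pool))], n_per_pool=3,
                           exclusion=())
        assert a == b

    def test_tie_break_lexicographic(self):
        g = nx.Graph([("B", "S1"), ("A", "S1")])
        hubs, _ = select_hubs(g, ["S1"], [["B", "A"]], n_per_pool=1, exclusion=())
        assert hubs[0].symbol == "A"

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_count_and_sort_oracle(self, seed):
        g = _random_graph(20, 0.25, seed)
        nodes = sorted(g.nodes)
        seeds, pool = nodes[:6], nodes[6:]
        hubs, _ = select_hubs(g, seeds, [pool], n_per_pool=4, exclusion=())
        counts = {c: sum(1 for s in seeds if g.has_edge(c, s)) for c in pool}
        expected = sorted(pool, key=lambda c: (-counts[c], c))[:4]
        assert [h.symbol for h in hubs] == expected
        assert [h.links_to_seed for h in hubs] == [counts[c] for c in expected]

    def test_invalid_n_per_pool(self):
        with pytest.raises(ValueError):
            select_hubs(self._graph(), ["S1"], [["H1"]], n_per_pool=0)


class TestTopology:
    def test_triangle_closed_form(self):
        rep = topology_metrics(nx.complete_graph(3))
        assert rep.clustering_coefficient == 1.0
        assert rep.avg_neighbors == 2.0
        assert rep.characteristic_path_length == 1.0
        assert rep.n_isolated == 0

    def test_path_graph_closed_form(self):
        rep = topology_metrics(nx.path_graph(3))
        assert rep.clustering_coefficient == 0.0
        assert rep.characteristic_path_length == pytest.approx((1 + 1 + 2) / 3)

    def test_isolated_nodes_counted_and_cpl_finite_pairs_only(self):
        g = nx.Graph([("A", "B")])
        g.add_node("C")
        rep = topology_metrics(g)
        assert rep.n_isolated == 1
        assert rep.characteristic_path_length == 1.0
        assert rep.avg_neighbors == pytest.approx(2 / 3)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            topology_metrics(nx.Graph())

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle(self, seed):
        g = _random_graph(12, 0.2, seed)
        rep = topology_metrics(g)
        nodes, edges = list(g.nodes), list(g.edges)
        assert rep.clustering_coefficient == pytest.approx(
            clustering_by_triangles(nodes, edges), abs=1e-12)
        assert rep.avg_neighbors == pytest.approx(2 * len(edges) / len(nodes),
                                                  abs=1e-12)
        oracle_cpl = path_length_mean(nodes, edges)
        if oracle_cpl is None:
            assert rep.characteristic_path_length is None
        else:
            assert rep.characteristic_path_length == pytest.approx(oracle_cpl,
                                                                   abs=1e-12)


class TestRegulatorSteps:
    def test_adjacent_is_one_and_self_is_zero(self):
        g = nx.Graph([("A", "R")])
        assert regulator_step_size(g, "A", "R") == 1
        assert regulator_step_size(g, "R", "R") == 0

    def test_unreachable_reported_distinctly(self):
        g = nx.Graph([("A", "B")])
        g.add_node("R")
        assert regulator_step_size(g, "A", "R") is None

    def test_missing_symbol_named(self):
        with pytest.raises(KeyError, match="ZZZ"):
            regulator_step_size(nx.Graph([("A", "B")]), "A", "ZZZ")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bfs_oracle(self, seed):
        g = _random_graph(12, 0.2, seed)
        nodes = sorted(g.nodes)
        reg = nodes[0]
        dist = bfs_distance(nodes, list(g.edges), reg)
        for node in nodes:
            assert regulator_step_size(g, node, reg) == dist.get(node)


class TestAssignLayers:
    def test_star_graph(self):
        g = nx.star_graph(4)
        layers = assign_layers(g, [0])
        assert layers[0] == 0
        assert all(layers[i] == 1 for i in range(1, 5))

    def test_disconnected_node_in_bottom_layer(self):
        g = nx.path_graph(3)
        g.add_node("iso")
        layers = assign_layers(g, [0])
        assert layers["iso"] == max(layers[n] for n in (0, 1, 2)) + 1

    def test_empty_top_nodes_rejected(self):
        with pytest.raises(ValueError):
            assign_layers(nx.path_graph(3), [])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_multisource_bfs_oracle(self, seed):
        g = _random_graph(14, 0.18, seed)
        nodes = sorted(g.nodes)
        tops = nodes[:2]
        layers = assign_layers(g, tops)
        per_source = [bfs_distance(nodes, list(g.edges), t) for t in tops]
        finite = {n: min(d[n] for d in per_source if n in d)
                  for n in nodes if any(n in d for d in per_source)}
        bottom = max(finite.values()) + 1
        for n in nodes:
            assert layers[n] == finite.get(n, bottom)


class TestEnrichment:
    def test_term_equals_universe_gives_p_one(self):
        uni = {f"G{i}" for i in range(10)}
        out = geneset_enrichment({"G1", "G2"}, {"all": uni}, uni)
        assert out.loc["all", "p"] == pytest.approx(1.0)
        assert out.loc["all", "overlap"] == 2

    def test_disjoint_term_gives_p_one(self):
        uni = {f"G{i}" for i in range(10)}
        out = geneset_enrichment({"G0", "G1"}, {"t": {"G8", "G9"}}, uni)
        assert out.loc["t", "p"] == pytest.approx(1.0)

    def test_full_overlap_matches_exhaustive_enumeration(self):
        # universe 10, query 5 == term 5: p = favourable / C(10,5)
        uni = [f"G{i}" for i in range(10)]
        term = set(uni[:5])
        n_total = 0
        n_hit = 0
        for draw in combinations(uni, 5):
            n_total += 1
            if len(set(draw) & term) >= 5:
                n_hit += 1
        out = geneset_enrichment(term, {"t": term}, set(uni))
        assert out.loc["t", "p"] == pytest.approx(n_hit / n_total, abs=1e-12)

    def test_p_monotone_nonincreasing_in_overlap(self):
        uni = {f"G{i}" for i in range(40)}
        term = {f"G{i}" for i in range(15)}
        ps = []
        for k in range(0, 11):
            query = {f"G{i}" for i in range(k)} | {f"G{30 + i}" for i in range(10 - k)}
            out = geneset_enrichment(query, {"t": term}, uni)
            ps.append(out.loc["t", "p"])
        assert all(ps[i + 1] <= ps[i] + 1e-12 for i in range(len(ps) - 1))
        assert all(0 <= p <= 1 for p in ps)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside universe"):
            geneset_enrichment({"X"}, {"t": {"A"}}, {"A", "B"})

    def test_bh_adjustment_present(self):
        uni = {f"G{i}" for i in range(20)}
        ann = {"a": {f"G{i}" for i in range(5)},
               "b": {f"G{i}" for i in range(10, 15)}}
        out = geneset_enrichment({"G0", "G1", "G2"}, ann, uni)
        assert (out["q"] >= out["p"] - 1e-15).all()
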