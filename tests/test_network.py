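import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cnvmir import network as nw
from cnvmir.types import ValidationError


def relevance_frame(flags: dict[str, tuple[bool, bool, bool]]) -> pd.DataFrame:
    return pd.DataFrame(
        [(g, *f) for g, f in flags.items()],
        columns=["gene", "expression", "function", "phenotype"],
    ).set_index("gene")


class TestMergeCandidates:
    def test_study_sized_lists_with_one_shared_gene(self):
        a = [f"a{i}" for i in range(34)] + ["shared"]
        b = [f"b{i}" for i in range(106)] + ["shared"]
        union, stats = nw.merge_candidates(a, b)
        assert stats == {"n_a": 35, "n_b": 107, "n_shared": 1, "n_union": 141}
        assert len(union) == 141

    def test_disjoint_lists(self):
        union, stats = nw.merge_candidates(["a"], ["b", "c"])
        assert stats["n_union"] == 3 and stats["n_shared"] == 0

    def test_identical_lists(self):
        union, stats = nw.merge_candidates(["a", "b"], ["b", "a"])
        assert union == {"a", "b"} and stats["n_union"] == 2


class TestRelevanceFilter:
    def test_single_flag_passes_min_one_not_min_two(self):
        ann = relevance_frame({"g": (True, False, False)})
        assert nw.apply_relevance_filter({"g"}, ann, 1) == {"g"}
        assert nw.apply_relevance_filter({"g"}, ann, 2) == set()

    def test_unannotated_gene_dropped(self):
        ann = relevance_frame({"g": (True, True, True)})
        assert nw.apply_relevance_filter({"x"}, ann, 1) == set()

    def test_twenty_gene_fixture_matches_hand_evaluation(self):
        rng = np.random.default_rng(4)
        flags = {f"g{i}": tuple(rng.random(3) < 0.5) for i in range(20)}
        ann = relevance_frame(flags)
        for min_c in (1, 2, 3):
            expected = {g for g, f in flags.items() if sum(f) >= min_c}
            assert nw.apply_relevance_filter(set(flags), ann, min_c) == expected


class TestGbaScore:
    def _graph(self, edges):
        g = nx.Graph()
        g.add_edges_from(edges)
        return g

    def test_weight_arithmetic(self):
        """1 candidate, 2 brain, 3 other neighbors -> 2.5 + 1.0 - 3.0 = 0.5."""
        g = self._graph(
            [("x", "c1"), ("x", "b1"), ("x", "b2"), ("x", "o1"), ("x", "o2"), ("x", "o3")]
        )
        scores = nw.gba_score(g, {"c1"}, {"x", "b1", "b2"})
        assert scores["x"].score == pytest.approx(0.5)
        assert scores["x"].n_candidate_neighbors == 1
        assert scores["x"].n_brain_neighbors == 2
        assert scores["x"].n_other_neighbors == 3

    def test_gene_absent_from_graph_unscored(self):
        g = self._graph([("a", "b")])
        scores = nw.gba_score(g, set(), {"a", "zzz"})
        assert "zzz" not in scores

    def test_single_candidate_neighbor(self):
        g = self._graph([("x", "c1")])
        assert nw.gba_score(g, {"c1"}, {"x"})["x"].score == pytest.approx(2.5)

    def test_overlapping_candidate_and_brain_sets_rejected(self):
        g = self._graph([("a", "b")])
        with pytest.raises(ValidationError):
            nw.gba_score(g, {"a"}, {"a", "b"})

    def test_matches_independent_neighbor_recount(self):
        rng = np.random.default_rng(17)
        g = nx.gnp_random_graph(120, 0.05, seed=3)
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})
        nodes = sorted(g.nodes)
        cands = set(nodes[:10])
        brain = set(nodes[10:50])
        scores = nw.gba_score(g, cands, brain)
        for gene, s in scores.items():
            nc = sum(1 for nb in g.neighbors(gene) if nb in cands)
            nb_ = sum(1 for nb in g.neighbors(gene) if nb in brain and nb not in cands)
            no = g.degree(gene) - nc - nb_
            assert s.score == pytest.approx(2.5 * nc + 0.5 * nb_ - no)


class TestBuildNetwork:
    def _setup(self):
        g = nx.Graph()
        g.add_weighted_edges_from(
            [
                ("cand1", "p_hi", 0.05),     # retained partner (score set below)
                ("p_hi", "p_lo", 0.03),
                ("cand2", "other1", 0.04),   # cand2's only neighbor is unretained
                ("p_border", "cand1", 0.02),
            ]
        )
        scores = {
            "p_hi": nw.GbaScore("p_hi", 5.0, 2, 0, 0),
            "p_lo": nw.GbaScore("p_lo", -1.0, 0, 1, 1),
            "p_border": nw.GbaScore("p_border", 1.5, 1, 0, 1),
        }
        return g, {"cand1", "cand2"}, scores

    def test_score_exactly_at_threshold_retained(self):
        g, cands, scores = self._setup()
        net = nw.build_network(g, cands, scores, retain_min=1.5)
        assert "p_border" in net.partners

    def test_candidate_without_retained_neighbors_dropped(self):
        g, cands, scores = self._setup()
        net = nw.build_network(g, cands, scores, retain_min=1.5)
        assert "cand2" not in net.nodes
        assert "p_lo" not in net.nodes

    def test_edge_closure(self):
        g, cands, scores = self._setup()
        net = nw.build_network(g, cands, scores, retain_min=1.5)
        for e in net.edges:
            assert e.gene_a in net.nodes and e.gene_b in net.nodes

    def test_raising_threshold_never_adds_nodes_or_edges(self):
        rng = np.random.default_rng(9)
        g = nx.gnp_random_graph(60, 0.1, seed=1)
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})
        nx.set_edge_attributes(g, 1.0, "weight")
        nodes = sorted(g.nodes)
        cands = set(nodes[:8])
        brain = set(nodes[8:40])
        scores = nw.gba_score(g, cands, brain)
        prev_nodes, prev_edges = None, None
        for retain in (-5.0, 0.0, 1.5, 3.0, 10.0):
            net = nw.build_network(g, cands, scores, retain)
            node_set = net.nodes
            edge_set = {e.pair for e in net.edges}
            if prev_nodes is not None:
                assert node_set <= prev_nodes
                assert edge_set <= prev_edges
            prev_nodes, prev_edges = node_set, edge_set

    def test_fifty_node_fixture_matches_brute_force(self):
        g = nx.gnp_random_graph(50, 0.12, seed=7)
        g = nx.relabel_nodes(g, {i: f"g{i:02d}" for i in g.nodes})
        nx.set_edge_attributes(g, 0.05, "weight")
        nodes = sorted(g.nodes)
        cands, brain = set(nodes[:6]), set(nodes[6:30])
        scores = nw.gba_score(g, cands, brain)
        net = nw.build_network(g, cands, scores, 1.5)
        keep = cands | {x for x, s in scores.items() if s.score >= 1.5}
        expected_edges = {
            tuple(sorted((a, b))) for a, b in g.edges if a in keep and b in keep
        }
        expected_nodes = {x for e in expected_edges for x in e}
        assert {e.pair for e in net.edges} == expected_edges
        assert net.nodes == expected_nodes


class TestRankByScore:
    def _net(self):
        g = nx.Graph()
        g.add_weighted_edges_from([("c", "p1", 1.0), ("p1", "p2", 1.0)])
        scores = {
            "p1": nw.GbaScore("p1", 5.0, 1, 1, 0),
            "p2": nw.GbaScore("p2", 4.5, 0, 1, 0),
        }
        return nw.build_network(g, {"c"}, scores, 1.5), g

    def test_descending_order(self):
        net, g = self._net()
        ranking = nw.rank_by_score(net, g, {"p1", "p2"})
        genes = [r[0] for r in ranking]
        assert genes.index("p1") < genes.index("p2")

    def test_candidates_receive_additive_score(self):
        net, g = self._net()
        ranking = dict(nw.rank_by_score(net, g, {"p1", "p2"}))
        # candidate c has one brain-relevant neighbor (p1): +0.5
        assert ranking["c"] == pytest.approx(0.5)

    def test_tie_breaks_lexicographically(self):
        g = nx.Graph()
        g.add_weighted_edges_from([("GENE_B", "c", 1.0), ("GENE_A", "c", 1.0)])
        scores = {
            "GENE_A": nw.GbaScore("GENE_A", 3.0, 1, 0, 0),
            "GENE_B": nw.GbaScore("GENE_B", 3.0, 1, 0, 0),
        }
        net = nw.build_network(g, {"c"}, scores, 1.5)
        ranking = nw.rank_by_score(net, g, {"GENE_A", "GENE_B"})
        top_two = [r[0] for r in ranking[:2]]
        assert top_two == ["GENE_A", "GENE_B"]

    def test_top_n_larger_than_network_returns_full_ranking(self):
        net, g = self._net()
        assert len(nw.rank_by_score(net, g, {"p1", "p2"}, top_n=100)) == len(net.nodes)

    def test_non_positive_top_n_rejected(self):
        net, g = self._net()
        with pytest.raises(ValidationError):
            nw.rank_by_score(net, g, {"p1", "p2"}, top_n=0)
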