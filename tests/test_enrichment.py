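from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from cnvmir import enrichment as en
from cnvmir import synth, targets as tg
from cnvmir.types import GeneSet, PipelineConfig


def fisher_oracle(a, b, c, d):
    """Exact right-tail p by enumerating all tables with the same margins."""
    n1, n2 = a + b, c + d
    m1 = a + c
    total = comb(n1 + n2, m1)
    p = Fraction(0)
    for k in range(a, min(n1, m1) + 1):
        if m1 - k <= n2:
            p += Fraction(comb(n1, k) * comb(n2, m1 - k), total)
    return p


class TestFilterGenesets:
    def test_bounds_inclusive(self):
        sets = [
            GeneSet(f"S{n}", "", frozenset(f"g{i}" for i in range(n)))
            for n in (10, 15, 900, 901)
        ]
        kept = en.filter_genesets(sets, 15, 900)
        assert {gs.set_id for gs in kept} == {"S15", "S900"}

    def test_empty_collection(self):
        assert en.filter_genesets([], 15, 900) == []

    def test_sizes_computed_within_universe(self):
        gs = GeneSet("S", "", frozenset({"a", "b", "c", "d"}))
        assert en.filter_genesets([gs], 3, 10, universe={"a", "b"}) == []
        kept = en.filter_genesets([gs], 2, 10, universe={"a", "b"})
        assert kept[0].genes == {"a", "b"}

    def test_survivor_count_matches_hand_count(self):
        rng = np.random.default_rng(8)
        sizes = rng.integers(5, 40, 30)
        sets = [
            GeneSet(f"S{i}", "", frozenset(f"g{j}" for j in range(sz)))
            for i, sz in enumerate(sizes)
        ]
        kept = en.filter_genesets(sets, 10, 25)
        assert len(kept) == sum(1 for sz in sizes if 10 <= sz <= 25)


class TestBuildContingency:
    def test_hand_trace_with_setless_gene_uncounted(self):
        cells = en.build_contingency(
            targets_i={"A", "B"},
            background={"A", "B", "C", "D", "E"},  # E belongs to no set
            gs_j=GeneSet("gs", "", frozenset({"A", "C"})),
            all_sets_union={"A", "B", "C", "D"},
        )
        assert (cells.a, cells.b, cells.c, cells.d) == (1, 1, 1, 1)

    def test_targets_disjoint_from_union(self):
        cells = en.build_contingency(
            {"X"}, {"X", "A", "B"}, GeneSet("gs", "", frozenset({"A"})), {"A", "B"}
        )
        assert cells.a == 0 and cells.b == 0

    def test_set_equal_to_union_gives_zero_b_and_d(self):
        cells = en.build_contingency(
            {"A"}, {"A", "B"}, GeneSet("gs", "", frozenset({"A", "B"})), {"A", "B"}
        )
        assert cells.b == 0 and cells.d == 0

    def test_empty_background_is_error(self):
        with pytest.raises(ValueError):
            en.build_contingency(set(), set(), GeneSet("gs", "", frozenset({"A"})), {"A"})


class TestFisherOneTailed:
    def test_unit_table_is_five_sixths(self):
        p = en.fisher_one_tailed(en.ContingencyCells(1, 1, 1, 1))
        assert p == pytest.approx(5 / 6)

    def test_a_zero_gives_p_one(self):
        p = en.fisher_one_tailed(en.ContingencyCells(0, 5, 3, 7))
        assert p == pytest.approx(1.0)

    def test_8_2_2_8_matches_enumeration(self):
        p = en.fisher_one_tailed(en.ContingencyCells(8, 2, 2, 8))
        assert p == pytest.approx(float(fisher_oracle(8, 2, 2, 8)), rel=1e-12)

    def test_matches_overlap_module_fisher(self):
        """The enrichment and overlap stages agree on identical tables."""
        from cnvmir.overlap import MechanismSet, overlap_test

        universe = {f"g{i}" for i in range(100)}
        ordered = sorted(universe)
        mech = MechanismSet("m", set(ordered[:10]))
        net = set(ordered[6:46])  # a=4, b=6, c=36, d=54
        t = overlap_test(mech, net, universe)
        cells = en.ContingencyCells(4, 6, 36, 54)
        assert t.p == pytest.approx(en.fisher_one_tailed(cells), rel=1e-12)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            en.ContingencyCells(-1, 0, 0, 0)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert en.bh_fdr([0.123]) == pytest.approx([0.123])

    def test_hand_computed_step_up(self):
        assert en.bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert en.bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_never_below_raw_p_and_monotone(self):
        rng = np.random.default_rng(1)
        p = rng.random(50)
        adj = en.bh_fdr(p)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            en.bh_fdr([0.5, 1.5])


def _results_frame(pvals, short=False):
    rows = []
    for (k, p) in pvals:
        rows.append(
            {
                "mirna_id": "m", "set_id": "S", "k_level": k, "short_list": short,
                "a": 1, "b": 1, "c": 1, "d": 1, "p": p, "fdr": p,
                "nominal_hit": p <= 0.01, "fdr25": p <= 0.25,
            }
        )
    return pd.DataFrame(rows)


class TestConsensusFilter:
    def test_two_of_three_runs_pass(self):
        res = _results_frame([(200, 0.005), (400, 0.02), (800, 0.009)])
        out = en.consensus_filter(res)
        assert bool(out["consensus"].iloc[0]) is True

    def test_one_of_three_runs_fails(self):
        res = _results_frame([(200, 0.02), (400, 0.02), (800, 0.001)])
        out = en.consensus_filter(res)
        assert bool(out["consensus"].iloc[0]) is False

    def test_short_list_uses_stricter_threshold(self):
        res = _results_frame([(200, 0.006)], short=True)
        assert bool(en.consensus_filter(res)["consensus"].iloc[0]) is False
        res = _results_frame([(200, 0.005)], short=True)
        assert bool(en.consensus_filter(res)["consensus"].iloc[0]) is True

    def test_empty_results(self):
        out = en.consensus_filter(pd.DataFrame())
        assert out.empty


class TestEnrichmentMapExport:
    def _consensus(self, sets, mirnas=("m1",)):
        return pd.DataFrame(
            [
                {"mirna_id": m, "set_id": s, "n_runs": 3, "n_nominal": 3,
                 "min_p": 0.001, "min_fdr": 0.01, "consensus": True, "fdr25": True}
                for s in sets
                for m in mirnas
            ]
        )

    def test_identical_sets_linked(self):
        gs = [GeneSet("A", "", frozenset({"x", "y"})), GeneSet("B", "", frozenset({"x", "y"}))]
        nodes, edges = en.enrichment_map_export(self._consensus(["A", "B"]), gs, 0.225)
        assert len(edges) == 1
        assert edges.iloc[0]["combined"] == pytest.approx(1.0)

    def test_disjoint_sets_unlinked(self):
        gs = [GeneSet("A", "", frozenset({"x"})), GeneSet("B", "", frozenset({"y"}))]
        _nodes, edges = en.enrichment_map_export(self._consensus(["A", "B"]), gs, 0.225)
        assert edges.empty

    def test_combined_coefficient_arithmetic(self):
        # |A|=4, |B|=6, |A&B|=2 -> combined = 0.5*(2/8) + 0.5*(2/4) = 0.375
        gs = [
            GeneSet("A", "", frozenset("abcd")),
            GeneSet("B", "", frozenset("cdefgh")),
        ]
        nodes, edges = en.enrichment_map_export(self._consensus(["A", "B"]), gs, 0.225)
        assert len(edges) == 1
        assert edges.iloc[0]["combined"] == pytest.approx(0.375)
        jac, ovl, comb_ = en.similarity_coefficients(gs[0].genes, gs[1].genes)
        assert comb_ == pytest.approx(0.5 * jac + 0.5 * ovl)

    def test_multi_mirna_flag(self):
        gs = [GeneSet("A", "", frozenset({"x"}))]
        nodes, _ = en.enrichment_map_export(self._consensus(["A"], mirnas=("m1", "m2")), gs, 0.225)
        assert bool(nodes.iloc[0]["multi_mirna"]) is True


class TestTypeIControl:
    def test_null_nominal_rate_near_alpha(self):
        """Without planted enrichment, the p <= 0.01 rate stays at the nominal
        order of magnitude (within 3 binomial SDs of 0.01)."""
        cfg = PipelineConfig()
        ps = []
        for seed in range(6):
            spec = synth.SynthSpec(
                seed=seed, n_background_mirnas=20, targets_per_mirna=300,
                n_genes=4000, n_genesets=50, geneset_size_range=(100, 250),
            )
            loci = synth.gen_mirna_annotation(spec)
            gsets = synth.gen_genesets(spec)
            r1, r2 = synth.gen_prediction_scores(spec, loci, gsets)
            known = {l.mirna_id for l in loci}
            p1 = tg.collapse_arms(tg.percentile_transform(r1, synth.TOOL_POLARITY[synth.TOOL1]), known)
            p2 = tg.collapse_arms(tg.percentile_transform(r2, synth.TOOL_POLARITY[synth.TOOL2]), known)
            integ = tg.integrate_tools(p1, p2)
            lists = {m: tg.topk(t, cfg.topk_levels) for m, t in integ.items() if t}
            background = set().union(
                *(set(l.lists[max(cfg.topk_levels)]) for l in lists.values())
            )
            region = {m: lists[m] for m in spec.region_mirna_ids if m in lists}
            res = en.run_enrichment(region, background, gsets, cfg)
            # one k level per miRNA keeps the tests independent
            ps.extend(res[res.k_level == 200]["p"].tolist())
        rate = np.mean([p <= 0.01 for p in ps])
        sd = np.sqrt(0.01 * 0.99 / len(ps))
        assert abs(rate - 0.01) <= 3 * sd, f"rate {rate:.4f} over {len(ps)} tests"
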