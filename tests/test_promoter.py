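"""Promoter binning, gene-level t-tests, and the p-value-weighted network."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import smokenet as sk
from smokenet.io import BetaMatrix, EdgeList, ProbeAnnotation, SampleSheet
from smokenet.promoter import (
    assign_promoter_probes,
    build_weighted_network,
    edge_weight,
    promoter_t_tests,
)


def _annotation(rows):
    table = pd.DataFrame(
        {"gene_symbols": [r[1] for r in rows],
         "placement": [r[2] for r in rows],
         "island_status": ["open_sea"] * len(rows)},
        index=pd.Index([r[0] for r in rows], name="probe_id"))
    return ProbeAnnotation(table)


class TestAssignPromoterProbes:
    def test_tss_categories_included_body_excluded(self):
        ann = _annotation([("cg1", ("RNASE4",), "TSS200"),
                           ("cg2", ("RNASE4",), "Body"),
                           ("cg3", ("OTHER",), "TSS1500")])
        mapping = assign_promoter_probes(ann)
        assert mapping == {"RNASE4": {"cg1"}, "OTHER": {"cg3"}}

    def test_multi_gene_probe_counted_for_each_gene(self):
        ann = _annotation([("cg1", ("A", "B"), "TSS200")])
        mapping = assign_promoter_probes(ann)
        assert mapping["A"] == {"cg1"} and mapping["B"] == {"cg1"}

    def test_widening_categories_grows_every_set(self):
        ann = _annotation([("cg1", ("A",), "TSS200"), ("cg2", ("A",), "5'UTR"),
                           ("cg3", ("B",), "TSS1500"), ("cg4", ("B",), "5'UTR")])
        narrow = assign_promoter_probes(ann)
        wide = assign_promoter_probes(ann, {"TSS200", "TSS1500", "5'UTR"})
        for gene in narrow:
            assert narrow[gene] <= wide[gene]


class TestPromoterTTests:
    def _toy(self, smoker_shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(20)]
        smoker = np.array([1] * 10 + [0] * 10)
        v = rng.uniform(0.3, 0.4, (4, 20))
        v[:2, smoker == 1] += smoker_shift
        bm = BetaMatrix(pd.DataFrame(v, index=["cg1", "cg2", "cg3", "cg4"], columns=samples))
        sheet = SampleSheet(pd.DataFrame(
            {"smoker": smoker, "slide": "s1", "plate": "p1"}, index=samples))
        mapping = {"A": {"cg1", "cg2"}, "B": {"cg3", "cg4"}}
        return bm, sheet, mapping

    def test_constant_gene_has_p_one(self):
        bm, sheet, _ = self._toy()
        v = bm.values.copy()
        v.iloc[0] = 0.3
        mapping = {"A": {"cg1"}}
        out = promoter_t_tests(BetaMatrix(v), sheet, mapping)
        assert out.loc["A", "raw_p"] == pytest.approx(1.0)

    def test_shifted_gene_detected(self):
        bm, sheet, mapping = self._toy(smoker_shift=-0.15)
        out = promoter_t_tests(bm, sheet, mapping)
        assert out.loc["A", "adjusted_p"] < 1e-4
        assert out.loc["A", "t_statistic"] < 0
        assert out.loc["B", "raw_p"] > 0.01

    def test_flattening_is_order_invariant(self):
        bm, sheet, mapping = self._toy(smoker_shift=-0.1)
        base = promoter_t_tests(bm, sheet, mapping)
        rng = np.random.default_rng(1)
        bm2 = BetaMatrix(bm.values.iloc[rng.permutation(4), rng.permutation(20)])
        perm = promoter_t_tests(bm2, sheet, mapping)
        np.testing.assert_allclose(base["raw_p"], perm["raw_p"], rtol=1e-10)

    def test_matches_flat_scipy_t_test(self):
        bm, sheet, mapping = self._toy(smoker_shift=-0.1)
        out = promoter_t_tests(bm, sheet, mapping)
        smoker = sheet.smoker_flags(bm.sample_ids).astype(bool)
        x = bm.values.loc[["cg1", "cg2"], smoker].to_numpy().ravel()
        y = bm.values.loc[["cg1", "cg2"], ~smoker].to_numpy().ravel()
        t_ref, p_ref = sk.unpaired_t_test(x, y)
        assert out.loc["A", "raw_p"] == pytest.approx(p_ref, rel=1e-10)
        assert out.loc["A", "t_statistic"] == pytest.approx(t_ref, rel=1e-10)

    def test_gene_with_too_few_values_dropped(self):
        bm, sheet, _ = self._toy()
        v = bm.values.copy()
        v.iloc[0, :] = np.nan
        v.iloc[0, 0] = 0.5
        out = promoter_t_tests(BetaMatrix(v), sheet, {"A": {"cg1"}, "B": {"cg3"}})
        assert "A" not in out.index and "B" in out.index

    def test_per_sample_mean_mode_changes_df(self):
        bm, sheet, mapping = self._toy(smoker_shift=-0.1)
        flat = promoter_t_tests(bm, sheet, mapping)
        avg = promoter_t_tests(bm, sheet, mapping, per_sample_mean=True)
        assert avg.loc["A", "n_smoker_values"] == 10
        assert flat.loc["A", "n_smoker_values"] == 20


class TestEdgeWeight:
    def test_closed_form_anchors(self):
        assert edge_weight(1e-10, 1e-10, 1e-10) == pytest.approx(1.0)
        assert edge_weight(1.0, 1.0, 1e-10) == pytest.approx(0.0)
        assert edge_weight(1e-5, 1e-5, 1e-10) == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(1e-30, 1.0), st.floats(1e-30, 1.0))
    def test_symmetric(self, a, b):
        p_min = min(a, b, 1e-3)
        assert edge_weight(a, b, p_min) == pytest.approx(edge_weight(b, a, p_min))

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(1e-20, 0.5), st.floats(1e-20, 0.5))
    def test_strictly_decreasing_in_each_p(self, a, b):
        p_min = 1e-25
        assert edge_weight(a, b, p_min) > edge_weight(min(1.0, a * 10), b, p_min)

    def test_degenerate_flat_table_rejected(self):
        with pytest.raises(ValueError, match="unweightable"):
            edge_weight(1.0, 1.0, 1.0)

    def test_floor_applied_to_underflow(self):
        w = edge_weight(0.0, 0.0, 0.0)
        assert w == pytest.approx(1.0)


class TestBuildWeightedNetwork:
    def _table(self, pvals):
        return pd.DataFrame({"adjusted_p": pd.Series(pvals)})

    def test_unmapped_endpoints_dropped(self):
        el = EdgeList([("A", "B"), ("B", "C"), ("C", "Z")])
        net = build_weighted_network(el, self._table({"A": 0.1, "B": 0.01, "C": 0.5}))
        assert net.number_of_edges() == 2 and "Z" not in net

    def test_weights_within_bounds_and_max_on_argmin_edge(self):
        el = EdgeList([("A", "B"), ("B", "C")])
        net = build_weighted_network(el, self._table({"A": 1e-6, "B": 1e-6, "C": 0.9}))
        ws = [d["weight"] for _, _, d in net.edges(data=True)]
        assert max(ws) == pytest.approx(1.0)
        assert min(ws) >= 0.0
        assert net.edges["A", "B"]["weight"] == pytest.approx(1.0)

    def test_node_attributes_carry_neg_log10(self):
        el = EdgeList([("A", "B")])
        net = build_weighted_network(el, self._table({"A": 1e-4, "B": 0.01}))
        assert net.nodes["A"]["neg_log10_p"] == pytest.approx(4.0)

    def test_weight_changes_follow_closed_form_under_rescaling(self):
        el = EdgeList([("A", "B"), ("B", "C")])
        p = {"A": 1e-4, "B": 1e-3, "C": 0.5}
        net1 = build_weighted_network(el, self._table(p))
        c = 0.1
        net2 = build_weighted_network(el, self._table({k: v * c for k, v in p.items()}))
        for u, v in net1.edges:
            lp = np.log([p[u] * c, p[v] * c])
            expect = lp.sum() / (2 * np.log(min(p.values()) * c))
            assert net2.edges[u, v]["weight"] == pytest.approx(expect)

    def test_empty_intersection_rejected(self):
        el = EdgeList([("X", "Y")])
        with pytest.raises(ValueError):
            build_weighted_network(el, self._table({"A": 0.5, "B": 0.2}))


class TestNullCalibrationSmall:
    def test_per_sample_mean_null_p_roughly_uniform(self):
        cs = sk.CohortSpec(n_probes=1000, n_genes=100, n_effect_probes=0,
                           slide_sd=0.0, plate_sd=0.0, seed=0)
        ps = sk.ReferencePanelSpec(n_probes=1000, n_celltype_probes=100, seed=0)
        bm, sheet, ann, _ = sk.generate_cohort(cs, ps)
        out = promoter_t_tests(bm, sheet, assign_promoter_probes(ann), per_sample_mean=True)
        from scipy.stats import kstest
        assert kstest(out["raw_p"], "uniform").pvalue > 0.001
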