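"""Binding matrix, Ward clustering, binomial enrichment, IQR filter, RF selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

import nucleocall as nc
from nucleocall.downstream import _cv_score
from nucleocall.intervals import BED3


def bed(rows):
    return pd.DataFrame(rows, columns=BED3)


class TestBindingMatrix:
    def test_toy_matrix_matches_brute_force_overlaps(self):
        dhs = bed([("chr1", i * 1000, i * 1000 + 300) for i in range(5)])
        trfs = {
            "A": bed([("chr1", 0, 5000)]),                      # covers all
            "B": bed([("chr1", 1100, 1200), ("chr1", 3100, 3200)]),  # rows 1 and 3
            "C": bed([("chr2", 0, 5000)]),                      # wrong chromosome
        }
        mat = nc.build_binding_matrix(dhs, trfs, min_bound=0)
        expected = pd.DataFrame({"A": [1] * 5, "B": [0, 1, 0, 1, 0]})
        # C has column sum 0 and is dropped by min_bound=0 (strict >)
        assert list(mat.columns) == ["A", "B"]
        assert (mat.to_numpy() == expected.to_numpy()).all()

    def test_column_thresholds(self):
        n = 1200
        dhs = bed([("chr1", i * 1000, i * 1000 + 100) for i in range(n)])
        trfs = {
            "kept": bed([("chr1", 0, 1001 * 1000)]),      # bound to 1001 rows
            "sparse": bed([("chr1", 0, 999 * 1000)]),     # bound to 999 rows
        }
        enrich = {"kept": 2.1, "sparse": 2.1}
        mat = nc.build_binding_matrix(dhs, trfs, enrichment=enrich, min_bound=1000)
        assert list(mat.columns) == ["kept"]

    def test_low_enrichment_column_dropped(self):
        dhs = bed([("chr1", i * 1000, i * 1000 + 100) for i in range(10)])
        trfs = {"X": bed([("chr1", 0, 10_000)])}
        mat = nc.build_binding_matrix(dhs, trfs, enrichment={"X": 1.5},
                                      min_bound=0, min_enrich=2.0)
        assert mat.shape[1] == 0


def planted_matrix(rng, n_per_block=60, n_trf=40, k=4, flip=0.0):
    """k blocks with disjoint characteristic factor sets, optional bit-flip noise."""
    rows, labels = [], []
    per = n_trf // k
    for c in range(k):
        profile = np.zeros(n_trf, dtype=int)
        profile[c * per:(c + 1) * per] = 1
        for _ in range(n_per_block):
            row = profile.copy()
            if flip:
                m = rng.random(n_trf) < flip
                row[m] = 1 - row[m]
            rows.append(row)
            labels.append(c)
    mat = pd.DataFrame(rows, columns=[f"TRF{j}" for j in range(n_trf)])
    return mat, np.array(labels)


class TestClusterDhs:
    def test_two_clean_blocks_recovered_exactly(self):
        rng = np.random.default_rng(0)
        mat, truth = planted_matrix(rng, k=2, n_trf=20)
        labels, top, union = nc.cluster_dhs(mat, k=2)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_four_blocks_with_noise(self):
        rng = np.random.default_rng(1)
        mat, truth = planted_matrix(rng, k=4, flip=0.05)
        labels, top, union = nc.cluster_dhs(mat, k=4)
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_identical_rows_single_cluster(self):
        mat = pd.DataFrame(np.ones((10, 5), dtype=int))
        labels, _, _ = nc.cluster_dhs(mat, k=1)
        assert set(labels) == {1}

    def test_row_order_invariance(self):
        rng = np.random.default_rng(2)
        mat, _ = planted_matrix(rng, k=3, n_trf=30, flip=0.02)
        la, _, _ = nc.cluster_dhs(mat, k=3)
        perm = rng.permutation(len(mat))
        lb, _, _ = nc.cluster_dhs(mat.iloc[perm].reset_index(drop=True), k=3)
        assert adjusted_rand_score(la.to_numpy()[perm], lb) == 1.0

    def test_top_trf_summary(self):
        rng = np.random.default_rng(3)
        mat, truth = planted_matrix(rng, k=2, n_trf=10)
        labels, top, union = nc.cluster_dhs(mat, k=2, top_n=3)
        # the block's own factors dominate its top list
        for c, names in top.items():
            block_rows = mat.loc[labels == c]
            assert set(names) <= set(mat.columns)
            assert block_rows[names[0]].mean() == 1.0
        assert len(union) <= 6

    def test_k_exceeding_rows_raises(self):
        with pytest.raises(ValueError):
            nc.cluster_dhs(pd.DataFrame(np.ones((3, 2))), k=5)


def brute_force_binomial_tail(x, n, p0):
    from math import comb
    return sum(comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(x, n + 1))


class TestClusterEnhancerTest:
    def make(self, sizes, hits):
        labels = pd.Series(np.repeat(np.arange(1, len(sizes) + 1), sizes))
        hit = pd.Series(np.zeros(len(labels), dtype=bool))
        start = 0
        for s, h in zip(sizes, hits):
            hit.iloc[start:start + h] = True
            start += s
        return labels, hit

    def test_known_value_half_null(self):
        # x=5 hits of n=10 in a cluster holding half the rows -> p ~ 0.6230
        labels, hit = self.make([50, 50], [5, 5])
        out = nc.cluster_enhancer_test(labels, hit).set_index("cluster")
        assert out.loc[1, "p_value"] == pytest.approx(0.623046875)

    def test_all_hits_in_one_cluster(self):
        labels, hit = self.make([50, 50], [10, 0])
        out = nc.cluster_enhancer_test(labels, hit).set_index("cluster")
        assert out.loc[1, "p_value"] == pytest.approx(2 ** -10)

    def test_zero_hits_pvalue_one(self):
        labels, hit = self.make([50, 50], [0, 7])
        out = nc.cluster_enhancer_test(labels, hit).set_index("cluster")
        assert out.loc[1, "p_value"] == pytest.approx(1.0)

    def test_matches_exact_summation_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            sizes = rng.integers(20, 300, 3)
            total_hits = int(rng.integers(1, 40))
            hits = rng.multinomial(total_hits, sizes / sizes.sum())
            labels, hit = self.make(list(sizes), list(hits))
            out = nc.cluster_enhancer_test(labels, hit).set_index("cluster")
            for c in (1, 2, 3):
                p0 = sizes[c - 1] / sizes.sum()
                expected = brute_force_binomial_tail(int(hits[c - 1]), total_hits, p0)
                assert out.loc[c, "p_value"] == pytest.approx(expected, rel=1e-9)


class TestIqrFilter:
    def test_extreme_outlier_dropped(self):
        vals = np.concatenate([np.arange(1, 101), [10_000]])
        keep = nc.iqr_outlier_filter(vals, t=50)
        assert keep.sum() == 100 and not keep[-1]

    def test_all_equal_nothing_dropped(self):
        keep = nc.iqr_outlier_filter(np.full(10, 3.0), t=1)
        assert keep.all()

    def test_infinite_threshold_keeps_everything(self):
        vals = np.concatenate([np.arange(1, 101), [1e12]])
        assert nc.iqr_outlier_filter(vals, t=np.inf).all()

    def test_threshold_arithmetic(self):
        # 1..100 plus two extremes: Q3 = 76.75, IQR = 50.5 -> cutoff at t=1 is 127.25
        vals = np.concatenate([np.arange(1, 101.0), [127.0, 128.0]])
        keep = nc.iqr_outlier_filter(vals, t=1)
        assert keep[-2] and not keep[-1]


class TestCoverageCorrelation:
    def tracks(self, va, vb, size=10_000):
        mk = lambda v: nc.DepthTrack.from_bedgraph(
            pd.DataFrame({"chrom": "chr1", "start": np.arange(len(v)) * 100,
                          "end": (np.arange(len(v)) + 1) * 100, "value": v}),
            {"chr1": size})
        return mk(va), mk(vb)

    def regions(self, n):
        return bed([("chr1", i * 100, (i + 1) * 100) for i in range(n)])

    def test_identical_tracks(self):
        a, b = self.tracks([1, 5, 2, 9], [1, 5, 2, 9])
        assert nc.coverage_correlation(a, b, self.regions(4)) == pytest.approx(1.0)

    def test_anticorrelated_tracks(self):
        a, b = self.tracks([1.0, 5, 2, 9], [9.0, 5, 8, 1])  # b = 10 - a
        assert nc.coverage_correlation(a, b, self.regions(4)) == pytest.approx(-1.0)

    def test_hand_computed_five_regions(self):
        va, vb = [3.0, 1, 4, 1, 5], [2.0, 7, 1, 8, 2]
        a, b = self.tracks(va, vb)
        expected = float(sps.pearsonr(va, vb)[0])
        assert nc.coverage_correlation(a, b, self.regions(5)) == pytest.approx(expected)

    def test_zero_variance_raises(self):
        a, b = self.tracks([2.0, 2, 2], [1.0, 2, 3])
        with pytest.raises(ValueError):
            nc.coverage_correlation(a, b, self.regions(3))


class TestGreedySelection:
    BASE = ["distance", "ctcf_vp", "ctcf_dhs", "ctcf_orient_vp_fwd", "ctcf_orient_dhs_fwd"]

    def test_causal_feature_selected_first(self):
        tbl, truth = nc.simulate_feature_table(
            800, ["causal"], [2.0], noise_sd=0.5, seed=0, n_decoys=8)
        trace = nc.greedy_rf_selection(tbl, self.BASE, truth["causal"] + truth["decoys"],
                                       "signal", n_add=1, seed=0)
        assert trace.loc[1, "feature"] == "causal"
        assert trace.loc[1, "score"] > trace.loc[0, "score"]

    def test_constant_target_r2_near_zero(self):
        tbl, truth = nc.simulate_feature_table(
            400, [], [], noise_sd=0.0, seed=1, n_decoys=4)
        tbl["signal"] = 1.0
        trace = nc.greedy_rf_selection(tbl, self.BASE, truth["decoys"], "signal",
                                       n_add=1, seed=1)
        assert abs(trace.loc[1, "score"]) < 0.05

    def test_pure_noise_auc_near_half(self):
        rng = np.random.default_rng(2)
        tbl, truth = nc.simulate_feature_table(
            600, [], [], noise_sd=1.0, seed=2, n_decoys=4)
        tbl["signal"] = rng.normal(0, 1, len(tbl))
        score = _cv_score(tbl[self.BASE], tbl["signal"].to_numpy(),
                          "classification", folds=3, seed=2)
        assert abs(score - 0.5) < 0.08

    def test_duplicated_selected_feature_adds_nothing(self):
        tbl, truth = nc.simulate_feature_table(
            600, ["causal"], [2.0], noise_sd=0.5, seed=3, n_decoys=3)
        tbl["causal_copy"] = tbl["causal"]
        trace = nc.greedy_rf_selection(
            tbl, self.BASE, ["causal", "causal_copy"] + truth["decoys"],
            "signal", n_add=2, seed=3)
        assert trace.loc[1, "feature"] == "causal"
        gain_second = trace.loc[2, "score"] - trace.loc[1, "score"]
        assert gain_second < 0.02  # within CV noise

    def test_reproducible_given_seed(self):
        tbl, truth = nc.simulate_feature_table(
            300, ["causal"], [1.0], noise_sd=0.5, seed=4, n_decoys=3)
        cands = truth["causal"] + truth["decoys"]
        a = nc.greedy_rf_selection(tbl, self.BASE, cands, "signal", n_add=2, seed=7)
        b = nc.greedy_rf_selection(tbl, self.BASE, cands, "signal", n_add=2, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_more_adds_than_candidates_warns_and_selects_all(self):
        tbl, truth = nc.simulate_feature_table(
            200, [], [], noise_sd=0.5, seed=5, n_decoys=2)
        trace = nc.greedy_rf_selection(tbl, self.BASE, truth["decoys"], "signal",
                                       n_add=10, seed=5)
        assert len(trace) == 3  # base + 2 candidates
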