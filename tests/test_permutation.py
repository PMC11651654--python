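"""Distance-preserving permutation, feature enrichment, TAD crossing, motif orientation."""

import numpy as np
import pandas as pd
import pytest

import nucleocall as nc
from nucleocall.permutation import count_overlapping, enrichment_table, filter_features

CHROM_SIZES = {"chr1": 10_000_000}


def interactions(entries, chrom="chr1", vp_width=1000, bin_width=250):
    """entries: (vp_start, bin_start) pairs."""
    rows = []
    for i, (vs, bs) in enumerate(entries):
        rows.append({"chrom": chrom, "vp_start": vs, "vp_end": vs + vp_width,
                     "bin_start": bs, "bin_end": bs + bin_width, "viewpoint_id": i})
    return pd.DataFrame(rows)


def random_interactions(n, rng, size=10_000_000):
    vs = rng.integers(3_000_000, size - 3_000_000, n)
    offs = rng.integers(5000, 2_000_000, n) * np.where(rng.random(n) < 0.5, 1, -1)
    return interactions(list(zip(vs, vs + offs)))


class TestPermutePirs:
    def test_singleton_distance_unchanged(self):
        inter = interactions([(1_000_000, 1_500_000)])
        perms = nc.permute_pirs(inter, n_perm=5, seed=0, chrom_sizes=CHROM_SIZES)
        for p in perms:
            assert p.loc[0, "start"] == 1_500_000

    def test_absolute_distance_multiset_preserved(self):
        rng = np.random.default_rng(1)
        inter = random_interactions(1000, rng)
        geo_d = np.abs((inter["bin_start"] + 125) - (inter["vp_start"] + 500))
        perms = nc.permute_pirs(inter, n_perm=3, seed=2, chrom_sizes=CHROM_SIZES)
        for p in perms:
            perm_d = np.abs(0.5 * (p["start"] + p["end"]) - p["vp_center"])
            assert sorted(np.round(perm_d)) == sorted(np.round(geo_d))

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(3)
        inter = random_interactions(200, rng)
        a = nc.permute_pirs(inter, n_perm=4, seed=9, chrom_sizes=CHROM_SIZES)
        b = nc.permute_pirs(inter, n_perm=4, seed=9, chrom_sizes=CHROM_SIZES)
        for pa, pb in zip(a, b):
            pd.testing.assert_frame_equal(pa, pb)

    def test_mean_distance_within_one_percent(self):
        rng = np.random.default_rng(4)
        inter = random_interactions(5000, rng)
        d0 = np.abs((inter["bin_start"] + 125) - (inter["vp_start"] + 500)).mean()
        perms = nc.permute_pirs(inter, n_perm=5, seed=1, chrom_sizes=CHROM_SIZES)
        for p in perms:
            d = np.abs(0.5 * (p["start"] + p["end"]) - p["vp_center"]).mean()
            assert abs(d - d0) / d0 < 0.01


class TestFeatureEnrichment:
    def test_genome_tiling_feature_gives_log2_zero(self):
        rng = np.random.default_rng(5)
        inter = random_interactions(300, rng)
        pirs = inter.rename(columns={"bin_start": "start", "bin_end": "end"})
        tiling = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10_000_000]})
        perms = nc.permute_pirs(inter, n_perm=10, seed=0, chrom_sizes=CHROM_SIZES)
        res = nc.feature_enrichment(pirs, tiling, perms)
        assert res.observed == 300
        assert res.expected_mean == 300
        assert res.log2_enrichment == pytest.approx(0.0)

    def test_fourfold_observed_gives_log2_two(self):
        pirs = pd.DataFrame({"chrom": ["chr1"] * 8,
                             "start": np.arange(8) * 10_000,
                             "end": np.arange(8) * 10_000 + 250})
        feature = pirs.copy()  # every true PIR overlaps
        # mock permuted sets overlapping exactly 2 of 8
        mock = pirs.copy()
        mock["start"] += 5000
        mock["end"] += 5000
        mock.loc[:1, ["start", "end"]] = pirs.loc[:1, ["start", "end"]].to_numpy()
        res = nc.feature_enrichment(pirs, feature, [mock, mock.copy()])
        assert res.observed == 8 and res.expected_mean == 2
        assert res.log2_enrichment == pytest.approx(2.0)

    def test_uniform_feature_density_matches_poisson_expectation(self):
        rng = np.random.default_rng(6)
        inter = random_interactions(400, rng)
        # point-like features scattered uniformly at density d per bp
        n_feat = 20_000
        size = CHROM_SIZES["chr1"]
        starts = np.sort(rng.integers(0, size - 10, n_feat))
        feats = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 10})
        perms = nc.permute_pirs(inter, n_perm=20, seed=7, chrom_sizes=CHROM_SIZES)
        res = nc.feature_enrichment(
            inter.rename(columns={"bin_start": "start", "bin_end": "end"}), feats, perms)
        # P(overlap) ~ 1 - exp(-d * (w + l)) per PIR (Poisson approximation)
        d = n_feat / size
        p_hit = 1 - np.exp(-d * (250 + 10))
        expect = 400 * p_hit
        sd = np.sqrt(400 * p_hit * (1 - p_hit))
        assert abs(res.expected_mean - expect) <= 3 * sd

    def test_empty_expected_reported_missing(self):
        pirs = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [250]})
        feats = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [250]})
        empty_perm = pd.DataFrame({"chrom": ["chr1"], "start": [5_000_000],
                                   "end": [5_000_250]})
        res = nc.feature_enrichment(pirs, feats, [empty_perm])
        assert np.isnan(res.log2_enrichment)

    def test_signal_value_filter(self):
        feats = pd.DataFrame({"chrom": ["chr1"] * 3, "start": [0, 100, 200],
                              "end": [50, 150, 250], "signalValue": [10, 25, 40]})
        kept = filter_features(feats, min_signal=25)
        assert kept["signalValue"].tolist() == [25, 40]

    def test_enrichment_table_runs_per_factor(self):
        rng = np.random.default_rng(8)
        inter = random_interactions(100, rng)
        pirs = inter.rename(columns={"bin_start": "start", "bin_end": "end"})
        perms = nc.permute_pirs(inter, n_perm=5, seed=3, chrom_sizes=CHROM_SIZES)
        feats = {"A": pirs.assign(signalValue=100.0),
                 "B": pirs.assign(start=pirs.start + 3000, end=pirs.end + 3000,
                                  signalValue=100.0)}
        tbl = enrichment_table(pirs, feats, perms)
        assert set(tbl["feature"]) == {"A", "B"}
        a = tbl.set_index("feature").loc["A"]
        assert a["observed"] == 100


class TestTadCrossing:
    def brute_force(self, inter, boundaries):
        n = 0
        for rec in inter.itertuples(index=False):
            lo = min(rec.vp_end, rec.bin_end)
            hi = max(rec.vp_start, rec.bin_start)
            for b in boundaries.itertuples(index=False):
                mid = 0.5 * (b.start + b.end)
                if rec.chrom == b.chrom and lo < mid < hi:
                    n += 1
                    break
        return n

    def test_no_boundaries_no_crossings(self):
        inter = interactions([(1_000_000, 1_500_000)])
        obs, exp = nc.tad_crossing(inter, pd.DataFrame(columns=["chrom", "start", "end"]), [])
        assert obs == 0

    def test_boundary_between_anchors_crosses(self):
        inter = interactions([(1_000_000, 1_500_000)])
        b = pd.DataFrame({"chrom": ["chr1"], "start": [1_200_000], "end": [1_200_010]})
        obs, _ = nc.tad_crossing(inter, b, [])
        assert obs == 1

    def test_matches_brute_force_on_random_layouts(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            inter = random_interactions(100, rng)
            starts = np.sort(rng.integers(0, 10_000_000, 30))
            bounds = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 10})
            obs, _ = nc.tad_crossing(inter, bounds, [])
            assert obs == self.brute_force(inter, bounds)

    def test_expected_from_permutations(self):
        rng = np.random.default_rng(10)
        inter = random_interactions(200, rng)
        starts = np.sort(rng.integers(0, 10_000_000, 20))
        bounds = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 10})
        perms = nc.permute_pirs(inter, n_perm=10, seed=4, chrom_sizes=CHROM_SIZES)
        obs, exp = nc.tad_crossing(inter, bounds, perms)
        assert exp > 0  # randomized placements still cross boundaries


class TestCtcfOrientation:
    def pir_frame(self, pir_start, vp_center=1_000_000, vp_id=0):
        return pd.DataFrame([{"chrom": "chr1", "start": pir_start,
                              "end": pir_start + 250, "vp_center": vp_center,
                              "viewpoint_id": vp_id}])

    def motif(self, pos, strand):
        return pd.DataFrame([{"chrom": "chr1", "start": pos, "end": pos + 19,
                              "strand": strand}])

    @pytest.mark.parametrize("pir_start,strand,towards", [
        (900_000, "+", True),    # + motif left of promoter points at it
        (1_100_000, "+", False),  # + motif right of promoter points away
        (1_100_000, "-", True),
        (900_000, "-", False),
    ])
    def test_towards_away_rule(self, pir_start, strand, towards):
        out = nc.ctcf_orientation(self.pir_frame(pir_start),
                                  self.motif(pir_start + 100, strand))
        row = out[out["side"] == "all"].iloc[0]
        assert (row["towards"], row["away"]) == ((1, 0) if towards else (0, 1))

    def test_upstream_downstream_stratification(self):
        pirs = pd.concat([self.pir_frame(900_000), self.pir_frame(1_100_000)],
                         ignore_index=True)
        motifs = pd.concat([self.motif(900_100, "+"), self.motif(1_100_100, "-")],
                           ignore_index=True)
        out = nc.ctcf_orientation(pirs, motifs, promoter_strands={0: "+"})
        sides = set(out["side"])
        assert {"upstream", "downstream", "all"} <= sides
        assert out.set_index("side").loc["all", "towards"] == 2

    def test_symmetric_placement_gives_half_towards(self):
        rng = np.random.default_rng(11)
        n = 2000
        pir_starts = 1_000_000 + rng.integers(5000, 500_000, n) * np.where(
            rng.random(n) < 0.5, 1, -1)
        pirs = pd.concat([self.pir_frame(int(s)) for s in pir_starts],
                         ignore_index=True)
        strands = np.where(rng.random(n) < 0.5, "+", "-")
        motifs = pd.DataFrame({"chrom": "chr1", "start": pir_starts + 100,
                               "end": pir_starts + 119, "strand": strands})
        out = nc.ctcf_orientation(pirs, motifs)
        frac = out.set_index("side").loc["all", "fraction_towards"]
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / n)
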