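"""Gold standards, binned LLS scoring and sigmoid calibration."""

import itertools
import math

import numpy as np
import pytest

import cofnet as cf
from cofnet.gold import BinnedLLS, BinStats, lls_from_counts


def random_pairs(rng, genes, k):
    out = set()
    while len(out) < k:
        a, b = rng.choice(len(genes), size=2, replace=False)
        out.add(cf.canonical_pair(genes[a], genes[b]))
    return out


class TestGoldStandard:
    def test_negative_count_small(self):
        gs = cf.build_gold_standard([("a", "b")], universe=["a", "b", "c"])
        assert gs.negative_count() == 2  # C(3,2) - 1

    def test_all_pairs_positive_leaves_no_negative(self):
        genes = ["a", "b", "c"]
        gs = cf.build_gold_standard(itertools.combinations(genes, 2), universe=genes)
        assert gs.negative_count() == 0

    def test_universe_defaults_to_positive_genes(self):
        gs = cf.build_gold_standard([("a", "b"), ("c", "d")])
        assert gs.universe == {"a", "b", "c", "d"}

    def test_positive_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            cf.build_gold_standard([("a", "z")], universe=["a", "b"])

    def test_counts_identity_property(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(40)]
        gs = cf.build_gold_standard(random_pairs(rng, genes, 55), universe=genes)
        assert gs.negative_count() + len(gs.positives) == 40 * 39 // 2


class TestUnion:
    def test_disjoint_union(self):
        a = cf.build_gold_standard([("a", "b")])
        b = cf.build_gold_standard([("c", "d")])
        assert len(cf.union_gold_standards([a, b]).positives) == 2

    def test_idempotent(self):
        a = cf.build_gold_standard([("a", "b"), ("b", "c")])
        u = cf.union_gold_standards([a, a])
        assert u.positives == a.positives and u.universe == a.universe

    def test_overlapping_sets_deduplicate(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(30)]
        p1 = random_pairs(rng, genes, 5)
        shared = set(itertools.islice(p1, 2))
        p2 = shared | random_pairs(rng, [f"h{i}" for i in range(20)], 2)
        a = cf.build_gold_standard(p1)
        b = cf.build_gold_standard(p2)
        u = cf.union_gold_standards([a, b])
        assert u.positives == p1 | p2
        assert len(u.positives) == 7


class TestBinAndScore:
    def setup_method(self):
        # 30 genes, evidence over 24 pairs, known positives
        self.genes = [f"g{i:02d}" for i in range(30)]
        rng = np.random.default_rng(0)
        self.positives = random_pairs(rng, self.genes, 40)
        self.gs = cf.build_gold_standard(self.positives, universe=self.genes)

    def test_bin_with_prior_ratio_gives_zero_lls(self):
        # p/n equal to P/N exactly -> ln(1) = 0
        P, N = 40, self.gs.negative_count()
        assert lls_from_counts(40, N, P, N) == pytest.approx(0.0, abs=1e-12)

    def test_continuity_correction_keeps_lls_finite(self):
        val = lls_from_counts(0, 1000, 234070, 26773505)
        assert math.isfinite(val) and val < 0
        assert val == pytest.approx(
            math.log((0.5 / 1000.5) / (234070 / 26773505)), rel=1e-12
        )

    def test_input_order_invariance(self):
        rng = np.random.default_rng(1)
        pairs = list(random_pairs(rng, self.genes, 120))
        scores = rng.normal(size=len(pairs))
        t1 = cf.EvidenceTable("a", dict(zip(pairs, scores.tolist())))
        shuffled = list(zip(pairs, scores.tolist()))
        rng.shuffle(shuffled)
        t2 = cf.EvidenceTable("a", dict(shuffled))
        b1 = cf.bin_and_score(t1, self.gs, bin_size=25)
        b2 = cf.bin_and_score(t2, self.gs, bin_size=25)
        assert [(b.mean_score, b.positives, b.negatives) for b in b1.bins] == [
            (b.mean_score, b.positives, b.negatives) for b in b2.bins
        ]

    def test_bin_totals_conserve_pairs(self):
        rng = np.random.default_rng(2)
        pairs = list(random_pairs(rng, self.genes, 130))
        t = cf.EvidenceTable("a", {p: float(s) for p, s in zip(pairs, rng.normal(size=130))})
        binned = cf.bin_and_score(t, self.gs, bin_size=40)
        assert sum(b.size for b in binned.bins) == 130

    def test_small_tail_merged_into_previous_bin(self):
        rng = np.random.default_rng(3)
        pairs = list(random_pairs(rng, self.genes, 130))
        t = cf.EvidenceTable("a", {p: float(s) for p, s in zip(pairs, rng.normal(size=130))})
        binned = cf.bin_and_score(t, self.gs, bin_size=100, min_tail=50)
        # tail of 30 < 50 merges: one bin of 130
        assert [b.size for b in binned.bins] == [130]

    def test_pairs_outside_universe_ignored(self):
        t = cf.EvidenceTable("a", {("zz1", "zz2"): 1.0})
        with pytest.raises(ValueError, match="universe"):
            cf.bin_and_score(t, self.gs)

    def test_hand_computed_single_bin(self):
        # 6 scored pairs, 2 positive; single bin
        genes = ["a", "b", "c", "d"]
        gs = cf.build_gold_standard([("a", "b"), ("c", "d")], universe=genes)
        P, N = 2, 4
        t = cf.EvidenceTable(
            "a",
            {
                ("a", "b"): 3.0,
                ("c", "d"): 2.5,
                ("a", "c"): 2.0,
                ("a", "d"): 1.0,
                ("b", "c"): 0.5,
                ("b", "d"): 0.1,
            },
        )
        binned = cf.bin_and_score(t, gs, bin_size=10)
        assert len(binned) == 1
        b = binned.bins[0]
        assert (b.positives, b.negatives) == (2, 4)
        assert b.lls == pytest.approx(math.log((2 / 4) / (P / N)), abs=1e-12)

    def test_independent_scores_give_near_zero_lls(self):
        """Evidence uncorrelated with the gold standard calibrates to ~0 LLS."""
        rng = np.random.default_rng(12)
        genes = [f"g{i:03d}" for i in range(200)]
        gs = cf.build_gold_standard(
            random_pairs(rng, genes, 400), universe=genes
        )
        pairs = list(random_pairs(rng, genes, 6000))
        t = cf.EvidenceTable(
            "null", {p: float(s) for p, s in zip(pairs, rng.normal(size=6000))}
        )
        binned = cf.bin_and_score(t, gs, bin_size=500)
        ok = 0
        for b in binned.bins:
            p, n = max(b.positives, 0.5), max(b.negatives, 0.5)
            se = math.sqrt(1 / p + 1 / n)
            ok += abs(b.lls) < 3 * se
        assert ok / len(binned.bins) >= 0.95


class TestCalibration:
    @staticmethod
    def make_binned(x, y):
        bins = [BinStats(float(xi), 1, 1, float(yi)) for xi, yi in zip(x, y)]
        return BinnedLLS(bins, 1000, 100, 1000)

    def test_recovers_exact_logistic(self):
        A, B, c, m = -1.0, 5.0, 2.5, 0.3
        x = np.linspace(-3, 3, 25)
        y = A + (B - A) / (1 + np.exp(-c * (x - m)))
        curve = cf.fit_calibration(self.make_binned(x, y))
        assert curve.lower == pytest.approx(A, rel=1e-4, abs=1e-4)
        assert curve.upper == pytest.approx(B, rel=1e-4)
        assert curve.slope == pytest.approx(c, rel=1e-4)
        assert curve.mid == pytest.approx(m, rel=1e-4, abs=1e-4)
        assert curve.fit_residual < 1e-6

    def test_decreasing_trend_fits_decreasing_curve(self):
        x = np.linspace(-2, 2, 20)
        y = 4.0 - 4.0 / (1 + np.exp(-3 * (x - 0.1)))
        curve = cf.fit_calibration(self.make_binned(x, y))
        assert curve.slope < 0
        pred = curve.predict(x)
        assert np.all(np.diff(pred) <= 1e-9)

    def test_flat_bins_accepted_as_degenerate(self):
        x = np.linspace(0, 1, 10)
        y = np.full(10, 2.0)
        curve = cf.fit_calibration(self.make_binned(x, y))
        assert curve.upper - curve.lower == pytest.approx(0.0, abs=1e-6)
        assert curve.fit_residual == pytest.approx(0.0, abs=1e-6)

    def test_too_few_bins_rejected(self):
        x = np.array([0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="4"):
            cf.fit_calibration(self.make_binned(x, x))

    def test_extrapolation_bounded_by_asymptotes(self):
        A, B, c, m = 0.0, 4.0, 3.0, 0.0
        x = np.linspace(-2, 2, 20)
        y = A + (B - A) / (1 + np.exp(-c * (x - m)))
        curve = cf.fit_calibration(self.make_binned(x, y))
        far = curve.predict(np.array([-100.0, 100.0]))
        assert far[0] == pytest.approx(A, abs=1e-6)
        assert far[1] == pytest.approx(B, abs=1e-6)
        assert np.all(curve.predict(np.linspace(-100, 100, 50)) <= B + 1e-9)

    def test_midpoint_maps_to_mean_of_asymptotes(self):
        curve = cf.CalibrationCurve(lower=-1.0, upper=5.0, slope=2.0, mid=0.7,
                                    fit_residual=0.0)
        assert curve.predict_one(0.7) == pytest.approx(2.0)

    def test_calibrate_preserves_monotonicity(self):
        curve = cf.CalibrationCurve(lower=0.0, upper=3.0, slope=1.5, mid=0.0,
                                    fit_residual=0.0)
        t = cf.EvidenceTable("a", {("a", "b"): -1.0, ("a", "c"): 0.0, ("b", "c"): 2.0})
        out = cf.calibrate_evidence(t, curve)
        assert out.scores[("a", "b")] < out.scores[("a", "c")] < out.scores[("b", "c")]

    def test_calibrated_scores_match_bin_lls(self, small_world):
        """A steep fitted curve reproduces each bin's LLS at the bin's mean score."""
        t = small_world.evidence_tables[0]
        binned = cf.bin_and_score(t, small_world.gold_standard, bin_size=200)
        curve = cf.fit_calibration(binned)
        for b in binned.bins:
            # within the spread of the empirical bin estimates around the fit
            assert abs(curve.predict_one(b.mean_score) - b.lls) < 4 * max(
                curve.fit_residual, 0.1
            )


class TestAdmission:
    @staticmethod
    def table_with_positive_lls(n_pos, n_nonpos=5):
        scores = {}
        for i in range(n_pos):
            scores[cf.canonical_pair(f"a{i:05d}", f"b{i:05d}")] = 1.0
        for i in range(n_nonpos):
            scores[cf.canonical_pair(f"c{i:05d}", f"d{i:05d}")] = -0.5
        return cf.EvidenceTable("x", scores)

    def test_exactly_min_links_admitted(self):
        res = cf.filter_admissible(self.table_with_positive_lls(2000))
        assert res.admitted and res.n_positive_lls == 2000

    def test_one_short_rejected(self):
        res = cf.filter_admissible(self.table_with_positive_lls(1999))
        assert not res.admitted

    def test_no_positive_lls_rejected(self):
        res = cf.filter_admissible(self.table_with_positive_lls(0))
        assert not res.admitted and len(res.table) == 0

    def test_filtered_table_keeps_only_positive_lls(self):
        res = cf.filter_admissible(self.table_with_positive_lls(3, 4), min_links=2)
        assert res.admitted
        assert all(v > 0 for v in res.table.scores.values())
        assert len(res.table) == 3
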