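"""ROC/AUC, confidence intervals, operating points, rank-sum, summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fibrillens.errors import ValidationError
from fibrillens.evaluation import (
    auc_ci,
    feature_summary,
    operating_point,
    ranksum_test,
    roc_curve,
)

TOY_SCORES = np.array([0.9, 0.6, 0.7, 0.5, 0.3])
TOY_LABELS = np.array([1, 1, 0, 0, 0])


class TestRocCurve:
    def test_perfect_separation(self):
        c = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert c.auc == pytest.approx(1.0)

    def test_identical_scores(self):
        c = roc_curve([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert c.auc == pytest.approx(0.5)

    def test_toy_mann_whitney_value(self):
        # AF {0.9, 0.6} vs non-AF {0.7, 0.5, 0.3}: 5 of 6 pairs ordered
        c = roc_curve(TOY_SCORES, TOY_LABELS)
        assert c.auc == pytest.approx(5 / 6)

    def test_sensitivity_monotone_in_threshold(self, rng):
        s = rng.random(60)
        y = (rng.random(60) < 0.4).astype(int)
        c = roc_curve(s, y)
        assert np.all(np.diff(c.se) >= 0)

    def test_trapezoid_equals_pair_counting(self, rng):
        for _ in range(20):
            s = rng.random(40)
            if rng.random() < 0.5:
                s = np.round(s, 1)  # force ties
            y = np.r_[np.ones(15), np.zeros(25)].astype(int)
            rng.shuffle(y)
            if y.sum() in (0, 40):
                continue
            c = roc_curve(s, y)
            pos, neg = s[y == 1], s[y == 0]
            u = (
                np.sum(pos[:, None] > neg[None, :])
                + 0.5 * np.sum(pos[:, None] == neg[None, :])
            ) / (pos.size * neg.size)
            assert c.auc == pytest.approx(u, abs=1e-12)

    def test_se_sp_match_naive_counting(self, rng):
        s = np.round(rng.random(50), 1)
        y = (rng.random(50) < 0.5).astype(int)
        if y.sum() in (0, 50):
            y[:3] = [0, 1, 1]
        c = roc_curve(s, y)
        for t, se, sp in zip(c.thresholds, c.se, c.sp):
            tp = sum(1 for si, yi in zip(s, y) if yi == 1 and si >= t)
            fn = sum(1 for si, yi in zip(s, y) if yi == 1 and si < t)
            tn = sum(1 for si, yi in zip(s, y) if yi == 0 and si < t)
            fp = sum(1 for si, yi in zip(s, y) if yi == 0 and si >= t)
            assert se == pytest.approx(tp / (tp + fn))
            assert sp == pytest.approx(tn / (tn + fp))

    def test_single_class_raises(self):
        with pytest.raises(ValidationError):
            roc_curve([0.1, 0.2], [1, 1])


class TestAucCi:
    def test_perfect_auc_collapses_interval(self):
        s = np.r_[np.linspace(0.6, 0.9, 200), np.linspace(0.1, 0.4, 200)]
        y = np.r_[np.ones(200), np.zeros(200)].astype(int)
        lo, hi = auc_ci(s, y)
        assert (lo, hi) == (1.0, 1.0)

    def test_hanley_mcneil_toy_arithmetic(self):
        lo, hi = auc_ci(TOY_SCORES, TOY_LABELS)
        a = 5 / 6
        q1 = a / (2 - a)
        q2 = 2 * a * a / (1 + a)
        se = np.sqrt((a * (1 - a) + (2 - 1) * (q1 - a * a) + (3 - 1) * (q2 - a * a)) / 6)
        assert lo == pytest.approx(max(0.0, a - 1.96 * se), abs=1e-10)
        assert hi == pytest.approx(min(1.0, a + 1.96 * se), abs=1e-10)

    def test_interval_contains_auc_and_shrinks_with_n(self, rng):
        s = rng.normal(size=60) + np.r_[np.ones(20), np.zeros(40)]
        y = np.r_[np.ones(20), np.zeros(40)].astype(int)
        c = roc_curve(s, y)
        lo, hi = c.ci95
        assert lo <= c.auc <= hi
        lo2, hi2 = auc_ci(np.tile(s, 2), np.tile(y, 2))
        assert hi2 - lo2 < hi - lo

    def test_delong_close_to_hanley_mcneil(self, rng):
        s = rng.normal(size=100) + np.r_[np.ones(40), np.zeros(60)]
        y = np.r_[np.ones(40), np.zeros(60)].astype(int)
        hm = auc_ci(s, y, method="hanley-mcneil")
        dl = auc_ci(s, y, method="delong")
        assert hm == pytest.approx(dl, abs=0.05)


class TestOperatingPoint:
    def test_perfect_classifier_case1(self):
        c = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        op = operating_point(c, 1)
        assert (op.se, op.sp) == (1.0, 1.0)

    def test_case2_matches_exhaustive_threshold_scan(self):
        c = roc_curve(TOY_SCORES, TOY_LABELS)
        op = operating_point(c, 2, sp_floor=2 / 3)
        # brute force over all thresholds
        best = None
        for t in c.thresholds:
            tp = np.sum((TOY_SCORES >= t) & (TOY_LABELS == 1)) / 2
            tn = np.sum((TOY_SCORES < t) & (TOY_LABELS == 0)) / 3
            if tn >= 2 / 3 and (best is None or tp > best[0]):
                best = (tp, tn)
        assert (op.se, op.sp) == pytest.approx(best)

    def test_case1_near_balanced_for_symmetric_scores(self, rng):
        s = np.r_[rng.normal(1.0, 1.0, 500), rng.normal(-1.0, 1.0, 500)]
        y = np.r_[np.ones(500), np.zeros(500)].astype(int)
        op = operating_point(roc_curve(s, y), 1)
        assert abs(op.se - op.sp) < 0.02

    def test_infeasible_floor_flags_point(self):
        c = roc_curve([0.6, 0.6, 0.6, 0.7], [0, 0, 0, 1])
        op = operating_point(c, 2, sp_floor=2.0)  # impossible floor
        assert not op.feasible


class TestRanksum:
    def test_identical_samples_not_significant(self):
        a = [1.0, 2.0, 3.0, 4.0]
        assert ranksum_test(a, list(a)) >= 0.99

    def test_fully_separated_samples(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0, 1, 20) + 100.0
        assert ranksum_test(a, b) < 0.001

    def test_small_n_matches_exact_permutation_enumeration(self, rng):
        a = list(rng.normal(size=4))
        b = list(rng.normal(size=5))
        p = ranksum_test(a, b)
        # brute force: rank-sum of group a over all label permutations
        pooled = a + b
        ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
        w_obs = sum(ranks[v] for v in a)
        mu = len(a) * (len(pooled) + 1) / 2
        count = total = 0
        for combo in itertools.combinations(range(9), 4):
            w = sum(ranks[pooled[i]] for i in combo)
            total += 1
            if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
                count += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_empty_sample_raises(self):
        with pytest.raises(ValidationError):
            ranksum_test([], [1.0])


class TestFeatureSummary:
    def test_single_record_per_class_reproduces_values(self):
        df = pd.DataFrame({"f1": [3.0, 7.0], "f2": [1.0, -1.0]}, index=["a", "b"])
        out = feature_summary(df, ["AF", "nonAF"])
        assert out.loc["f1", "af_median"] == 3.0
        assert out.loc["f1", "nonaf_median"] == 7.0

    def test_quartiles_match_interpolation_oracle(self, rng):
        vals = rng.normal(size=30)
        df = pd.DataFrame({"f": np.r_[vals, rng.normal(size=5)]})
        labels = ["AF"] * 30 + ["nonAF"] * 5
        out = feature_summary(df, labels)

        def percentile(sorted_vals, q):
            # linear interpolation between order statistics
            h = (len(sorted_vals) - 1) * q
            lo = int(np.floor(h))
            hi = min(lo + 1, len(sorted_vals) - 1)
            return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])

        sv = sorted(vals)
        assert out.loc["f", "af_q25"] == pytest.approx(percentile(sv, 0.25), abs=1e-12)
        assert out.loc["f", "af_median"] == pytest.approx(percentile(sv, 0.5), abs=1e-12)
        assert out.loc["f", "af_q75"] == pytest.approx(percentile(sv, 0.75), abs=1e-12)

    def test_significance_stars(self, rng):
        n = 40
        df = pd.DataFrame(
            {
                "shifted": np.r_[rng.normal(5, 1, n), rng.normal(0, 1, n)],
                "same": rng.normal(0, 1, 2 * n),
            }
        )
        labels = ["AF"] * n + ["nonAF"] * n
        out = feature_summary(df, labels)
        assert bool(out.loc["shifted", "significant"])
        assert not bool(out.loc["same", "significant"])
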