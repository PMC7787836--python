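"""Diagnostic-metrics engine: count arithmetic, CIs, Bayes sweeps, AUC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairdx import (
    ConfusionCounts,
    DiagnosticReport,
    auc,
    confusion,
    lr_ci,
    pathology_accuracy,
    point_metrics,
    predictive_values_at,
    wald_ci,
)

# the testing-cohort confusion table recovered from n=84, 85.7% malignant,
# sensitivity 71/72 and specificity 7/12
TESTING = ConfusionCounts(tp=71, fn=1, tn=7, fp=5)


class TestConfusion:
    def test_perfect_and_inverted_calls(self):
        y = np.array([1, 1, 0, 0, 1])
        assert confusion(y, y) == ConfusionCounts(tp=3, fn=0, tn=2, fp=0)
        assert confusion(1 - y, y) == ConfusionCounts(tp=0, fn=3, tn=0, fp=2)

    def test_count_recovery_from_rates(self):
        # 84 samples, 72 positives; 71 of 72 positives and 7 of 12 negatives correct
        calls = np.array([1] * 71 + [0] * 1 + [0] * 7 + [1] * 5)
        labels = np.array([1] * 72 + [0] * 12)
        assert confusion(calls, labels) == TESTING

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1, 0, 1])


class TestPointMetrics:
    def test_testing_cohort_ratios(self):
        pm = point_metrics(TESTING)
        assert round(pm["plr"], 3) == 2.367
        assert round(pm["nlr"], 3) == 0.024
        assert round(100 * pm["ppv"], 1) == 93.4
        assert round(100 * pm["npv"], 1) == 87.5
        assert round(100 * pm["accuracy"], 1) == 92.9
        assert round(100 * pm["sensitivity"], 1) == 98.6
        assert round(100 * pm["specificity"], 1) == 58.3

    def test_training_cohort_plr(self):
        # counts recovered from n=929, 85.8% malignant, sens 93.4%, spec 84.1%
        pm = point_metrics(ConfusionCounts(tp=744, fn=53, tn=111, fp=21))
        assert round(pm["plr"], 3) == 5.868
        assert round(pm["nlr"], 3) == 0.079
        assert round(100 * pm["ppv"], 1) == 97.3
        assert round(100 * pm["npv"], 1) == 67.7

    def test_undefined_metrics_flagged(self):
        pm = point_metrics(ConfusionCounts(tp=5, fn=0, tn=0, fp=5))
        assert math.isnan(pm["nlr"])
        assert "nlr" in pm["undefined"]

    @settings(deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 400)] * 4))
    def test_matches_bruteforce_2x2(self, cells):
        """Oracle equivalence against direct rational 2x2 arithmetic."""
        tp, fn, tn, fp = cells
        c = ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)
        pm = point_metrics(c)
        from fractions import Fraction

        def frac(num, den):
            return float(Fraction(num, den)) if den else None

        for key, val in {
            "sensitivity": frac(tp, tp + fn),
            "specificity": frac(tn, tn + fp),
            "accuracy": frac(tp + tn, tp + fn + tn + fp) if (tp + fn + tn + fp) else None,
            "ppv": frac(tp, tp + fp),
            "npv": frac(tn, tn + fn),
        }.items():
            if val is None:
                assert math.isnan(pm[key])
            else:
                assert pm[key] == pytest.approx(val, abs=1e-15)

    @settings(deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(1, 400)] * 4))
    def test_plr_nlr_relation(self, cells):
        """PLR > 1 iff NLR < 1 whenever the test is informative (sens+spec > 1)."""
        c = ConfusionCounts(*cells)
        pm = point_metrics(c)
        if pm["sensitivity"] + pm["specificity"] > 1:
            assert pm["plr"] > 1
            assert pm["nlr"] < 1


class TestWaldCI:
    def test_printed_interval_above_one(self):
        lo, hi = wald_ci(71 / 72, 72)
        assert (round(100 * lo, 1), round(100 * hi, 1)) == (95.9, 101.3)

    def test_printed_interval_wide(self):
        lo, hi = wald_ci(7 / 12, 12)
        assert (round(100 * lo, 1), round(100 * hi, 1)) == (30.4, 86.2)

    def test_negative_lower_bound(self):
        lo, hi = wald_ci(2 / 12, 12)  # specificity 16.7% on 12 negatives
        assert (round(100 * lo, 1), round(100 * hi, 1)) == (-4.4, 37.8)

    def test_degenerate_p_one(self):
        assert wald_ci(1.0, 50) == (1.0, 1.0)

    def test_clipping_optional(self):
        assert wald_ci(71 / 72, 72, clip=True)[1] == 1.0

    def test_width_shrinks_with_n(self):
        widths = [wald_ci(0.3, n)[1] - wald_ci(0.3, n)[0] for n in (10, 20, 40, 80)]
        assert all(a > b for a, b in zip(widths, widths[1:]))


class TestLikelihoodRatioCI:
    def test_testing_cohort_log_method(self):
        ci = lr_ci(TESTING)
        assert tuple(round(v, 3) for v in ci["plr"]) == (1.211, 4.625)
        assert tuple(round(v, 3) for v in ci["nlr"]) == (0.003, 0.177)

    def test_training_cohort_log_method(self):
        ci = lr_ci(ConfusionCounts(tp=744, fn=53, tn=111, fp=21))
        assert tuple(round(v, 3) for v in ci["plr"]) == (3.962, 8.689)
        assert tuple(round(v, 3) for v in ci["nlr"]) == (0.060, 0.104)

    def test_uninformative_test_ci_contains_one(self):
        ci = lr_ci(ConfusionCounts(tp=50, fn=50, tn=50, fp=50))
        assert ci["plr"][0] < 1.0 < ci["plr"][1]

    def test_zero_cell_flagged(self):
        with pytest.raises(ValueError, match="zero"):
            lr_ci(ConfusionCounts(tp=10, fn=0, tn=5, fp=5))


class TestPredictiveValues:
    @pytest.mark.parametrize(
        "prev, ppv_pct, npv_pct", [(0.20, 37, 99), (0.40, 61, 98)]
    )
    def test_prevalence_sweep_endpoints(self, prev, ppv_pct, npv_pct):
        """20-40% prevalence sweep with the count-exact sens/spec of the test cohort."""
        ppv, npv = predictive_values_at(71 / 72, 7 / 12, prev)
        assert round(100 * ppv) == ppv_pct
        assert round(100 * npv) == npv_pct

    def test_zero_prevalence(self):
        assert predictive_values_at(0.9, 0.8, 0.0)[1] == 1.0

    @settings(deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(1, 200)] * 4))
    def test_bayes_counts_consistency(self, cells):
        """Bayes at the cohort prevalence reproduces PPV/NPV computed from counts."""
        c = ConfusionCounts(*cells)
        pm = point_metrics(c)
        ppv, npv = predictive_values_at(pm["sensitivity"], pm["specificity"], pm["prevalence"])
        assert ppv == pytest.approx(pm["ppv"], abs=1e-12)
        assert npv == pytest.approx(pm["npv"], abs=1e-12)


class TestAUC:
    def test_perfect_ranking(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_exhaustive_pair_counting_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = 12
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc(scores, labels) == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.9], [1, 1])


class TestPathologyAccuracy:
    def test_stratified_counts(self):
        calls = np.array([1] * 7 + [0] * 5 + [1, 1])
        labels = np.array([1] * 12 + [1, 1])
        path = np.array(["follicular adenoma"] * 12 + ["papillary"] * 2)
        tab = pathology_accuracy(calls, labels, path)
        assert tab.loc["follicular adenoma", "display"] == "7/12 (58.3%)"
        assert tab.loc["papillary", "display"] == "2/2 (100.0%)"

    def test_empty_stratum_absent(self):
        tab = pathology_accuracy([1], [1], ["anaplastic"])
        assert list(tab.index) == ["anaplastic"]


class TestDiagnosticReport:
    def test_estimates_inside_unclipped_cis(self):
        rep = DiagnosticReport(TESTING)
        df = rep.summary()
        for m in ("sensitivity", "specificity", "accuracy", "plr", "nlr", "ppv", "npv"):
            row = df.loc[m]
            assert row.ci_low <= row.estimate <= row.ci_high
        assert df.loc["sensitivity", "ci_high"] > 1.0  # deliberately not clipped

    def test_from_calls_includes_auc(self):
        rep = DiagnosticReport.from_calls([1, 1, 0, 0], [1, 1, 0, 0], scores=[0.9, 0.8, 0.2, 0.1])
        assert rep.auc.estimate == 1.0
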