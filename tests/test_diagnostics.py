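"""ROC construction, cutoff selection, likelihood ratios and Bayes updates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from myoscreen import (
    ConfusionMatrix, empirical_roc, auc_ci, youden_optimal, confusion_at,
    confusion_from_rates, likelihood_ratios, diagnostic_odds_ratio,
    performance_from_counts, posttest, screen_subject,
)

scores = st.lists(
    st.floats(min_value=-5, max_value=5, allow_nan=False), min_size=1, max_size=12
)


def brute_force_auc(d, nd):
    """Exhaustive pairwise comparison, ties counted one half."""
    total = 0.0
    for x in d:
        for y in nd:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(d) * len(nd))


class TestRoc:
    def test_tied_pair_example(self):
        roc = empirical_roc([2, 3], [1, 2])
        assert roc.auc == pytest.approx(0.875)

    def test_separated_and_identical(self):
        assert empirical_roc([3, 4], [1, 2]).auc == 1.0
        assert empirical_roc([1, 2, 3], [1, 2, 3]).auc == 0.5

    def test_sensitivity_monotone_and_endpoints(self):
        roc = empirical_roc([1.5, 2.5, 2.5], [0.5, 1.0, 2.0])
        assert (np.diff(roc.se) >= 0).all()  # se non-decreasing as cutoff drops
        assert roc.se[0] == 0 and roc.sp[0] == 1  # sentinel above max score
        assert roc.se[-1] == 1  # lowest observed cutoff catches all diseased

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            empirical_roc([], [1.0])

    @given(scores, scores)
    @settings(deadline=None, max_examples=100)
    def test_auc_is_mann_whitney(self, d, nd):
        roc = empirical_roc(d, nd, ci_method="hanley_mcneil")
        assert roc.auc == pytest.approx(brute_force_auc(d, nd), abs=1e-12)

    @given(scores, scores)
    @settings(deadline=None, max_examples=100)
    def test_auc_equals_trapezoid_area(self, d, nd):
        roc = empirical_roc(d, nd, ci_method="hanley_mcneil")
        fpr = 1 - roc.sp
        area = np.trapezoid(roc.se, fpr)
        assert roc.auc == pytest.approx(area, abs=1e-12)

    def test_mann_whitney_agreement_on_random_batch(self, rng):
        # AUC equals U/(n1*n0) from scipy on a thousand random instances
        for _ in range(1000):
            n1, n0 = rng.integers(1, 9, size=2)
            d = rng.integers(0, 6, size=n1).astype(float)  # ties likely
            nd = rng.integers(0, 6, size=n0).astype(float)
            u = stats.mannwhitneyu(d, nd, alternative="two-sided").statistic
            got = empirical_roc(d, nd, ci_method="hanley_mcneil").auc
            assert got == pytest.approx(u / (n1 * n0), abs=1e-12)


class TestAucCi:
    def test_hanley_mcneil_study_size(self):
        lo, hi = auc_ci(0.843, 23, 60, method="hanley_mcneil")
        assert (round(lo, 3), round(hi, 3)) == (0.736, 0.950)

    def test_clipping(self):
        lo, hi = auc_ci(1.0, 5, 5, method="hanley_mcneil")
        assert hi == 1.0

    def test_delong_requires_scores(self):
        with pytest.raises(ValueError, match="raw scores"):
            auc_ci(0.8, 10, 10, method="delong")

    def test_delong_matches_bootstrap_se(self, rng):
        # DeLong SE within 10% of a 10^4-resample bootstrap SE
        d = rng.normal(1.2, 0.6, size=23)
        nd = rng.normal(0.0, 0.6, size=60)
        roc = empirical_roc(d, nd, ci_method="delong")
        delong_se = (roc.auc_ci[1] - roc.auc_ci[0]) / (2 * 1.96)
        n_boot = 10_000
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            db = rng.choice(d, size=d.size, replace=True)
            nb = rng.choice(nd, size=nd.size, replace=True)
            aucs[b] = (db[:, None] > nb[None, :]).mean()
        assert delong_se == pytest.approx(aucs.std(ddof=1), rel=0.10)


class TestYouden:
    def test_perfect_separation(self):
        roc = empirical_roc([1.5, 1.8, 2.0], [0.8, 0.9, 1.4])
        best = youden_optimal(roc)
        assert best.cutoff == 1.5
        assert best.se == 1.0 and best.sp == 1.0 and best.youden_j == 1.0

    def test_degenerate_flag(self):
        best = youden_optimal(empirical_roc([2, 2], [2, 2]))
        assert best.degenerate and best.youden_j == 0.0

    def test_matches_exhaustive_search(self, rng):
        for _ in range(300):
            n1, n0 = rng.integers(1, 7, size=2)
            d = rng.integers(0, 5, size=n1).astype(float)
            nd = rng.integers(0, 5, size=n0).astype(float)
            best = youden_optimal(empirical_roc(d, nd, ci_method="hanley_mcneil"))
            best_j = max(
                (d >= c).mean() + (nd < c).mean() - 1
                for c in np.unique(np.concatenate([d, nd]))
            )
            assert best.youden_j == pytest.approx(best_j, abs=1e-12)

    def test_tie_breaks_toward_higher_sensitivity_then_lower_cutoff(self):
        # cutoffs 1 and 2 both give J = 0.5; cutoff 1 has se 1.0
        roc = empirical_roc([1, 2], [0, 1.5], ci_method="hanley_mcneil")
        best = youden_optimal(roc)
        assert best.cutoff == 1.0 and best.se == 1.0


class TestConfusion:
    def test_enumeration_under_ge_rule(self):
        cm = confusion_at([2, 3], [1, 2], cutoff=2)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (2, 0, 1, 1)

    def test_extreme_cutoffs(self):
        low = confusion_at([2, 3], [1, 2], cutoff=0)
        assert low.fn == 0 and low.tn == 0
        high = confusion_at([2, 3], [1, 2], cutoff=10)
        assert high.tp == 0 and high.fp == 0

    def test_from_printed_rates(self):
        cm = confusion_from_rates(0.696, 0.967, 23, 60)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (16, 7, 2, 58)


class TestLikelihoodRatios:
    def test_study_point_estimates_and_cis(self, study_counts):
        lr_pos, lr_neg = likelihood_ratios(study_counts)
        assert round(lr_pos.value, 1) == 20.9
        assert (round(lr_pos.ci[0], 1), round(lr_pos.ci[1], 1)) == (5.2, 83.7)
        # exact fractions give 0.315 (printed 0.32 is not an exact fraction)
        assert lr_neg.value == pytest.approx((7 / 23) / (58 / 60), abs=1e-12)
        assert (round(lr_neg.ci[0], 2), round(lr_neg.ci[1], 2)) == (0.17, 0.59)

    def test_perfect_test_flagged(self):
        lr_pos, lr_neg = likelihood_ratios(ConfusionMatrix(10, 0, 0, 10))
        assert lr_pos.unbounded and math.isinf(lr_pos.value)
        assert lr_neg.unbounded and lr_neg.value == 0.0

    def test_continuity_correction_unflags(self):
        lr_pos, lr_neg = likelihood_ratios(ConfusionMatrix(10, 0, 0, 10), correction=True)
        assert not lr_pos.unbounded and math.isfinite(lr_pos.value)
        assert not lr_neg.unbounded and lr_neg.value > 0


class TestDor:
    def test_study_values(self, study_counts):
        dor = diagnostic_odds_ratio(study_counts)
        assert round(dor.value, 1) == 66.3
        assert round(dor.ci[0], 1) == 12.5

    def test_second_comparison(self):
        dor = diagnostic_odds_ratio(ConfusionMatrix(18, 5, 2, 33))
        assert round(dor.value, 1) == 59.4

    def test_reciprocal_symmetry(self):
        a = diagnostic_odds_ratio(ConfusionMatrix(8, 3, 3, 8)).value
        b = diagnostic_odds_ratio(ConfusionMatrix(3, 8, 8, 3)).value
        assert a == pytest.approx(1 / b, rel=1e-12)

    @given(st.integers(1, 40), st.integers(1, 40), st.integers(1, 40), st.integers(1, 40))
    @settings(deadline=None)
    def test_dor_equals_lr_quotient(self, tp, fn, fp, tn):
        cm = ConfusionMatrix(tp, fn, fp, tn)
        lr_pos, lr_neg = likelihood_ratios(cm)
        dor = diagnostic_odds_ratio(cm)
        assert dor.value == pytest.approx(lr_pos.value / lr_neg.value, rel=1e-9)
        perf = performance_from_counts(cm)
        assert -1 <= perf.youden_j <= 1


class TestBayes:
    def test_study_worked_example(self, study_counts):
        lr_pos, _ = likelihood_ratios(study_counts)
        result = posttest(0.15, lr_pos.value)
        assert round(result.pretest_odds, 2) == 0.18
        assert round(result.posttest_prob, 3) == 0.786

    def test_uninformative_and_simple(self):
        assert posttest(0.37, 1.0).posttest_prob == pytest.approx(0.37)
        assert posttest(0.5, 3.0).posttest_prob == pytest.approx(0.75)

    def test_boundary_guards(self):
        for p in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                posttest(p, 2.0)
        with pytest.raises(ValueError):
            posttest(0.5, 0.0)

    @given(st.floats(min_value=0.01, max_value=0.99), st.floats(min_value=1.0, max_value=50))
    @settings(deadline=None)
    def test_monotone_updating(self, p, lr):
        assert posttest(p, lr).posttest_prob >= p - 1e-12

    @given(
        st.floats(min_value=0.01, max_value=0.99),
        st.floats(min_value=0.1, max_value=20),
        st.floats(min_value=0.1, max_value=20),
    )
    @settings(deadline=None)
    def test_bayes_composition(self, p, lr_a, lr_b):
        chained = posttest(posttest(p, lr_a).posttest_prob, lr_b).posttest_prob
        direct = posttest(p, lr_a * lr_b).posttest_prob
        assert chained == pytest.approx(direct, rel=1e-9)


class TestScreenSubject:
    def test_positive_branch_reproduces_worked_example(self, study_counts):
        perf = performance_from_counts(study_counts, cutoff=1.30)
        label, bayes = screen_subject(1.96, 1.30, 0.15, perf)
        assert label == "positive"
        assert round(bayes.posttest_prob, 3) == 0.786

    def test_negative_branch_applies_lr_neg(self, study_counts):
        perf = performance_from_counts(study_counts, cutoff=1.30)
        label, bayes = screen_subject(0.92, 1.30, 0.15, perf)
        assert label == "negative"
        expected_odds = (0.15 / 0.85) * perf.lr_neg.value
        assert bayes.posttest_prob == pytest.approx(expected_odds / (1 + expected_odds))

    def test_ratio_at_cutoff_is_positive(self, study_counts):
        perf = performance_from_counts(study_counts, cutoff=1.30)
        assert screen_subject(1.30, 1.30, 0.15, perf)[0] == "positive"
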