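"""Rank tests, survival analysis, ROC, the multivariate remission model
and the endpoint summary table."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirsense import (
    ResponseCoding,
    ValidationError,
    km_curve,
    logrank,
    median_survival,
    multivariate_remission_fit,
    response_correlation,
    roc_auc,
    score_cohort,
    summary_table,
    wilcoxon_one_sided,
)
from mirsense.scoring import gcb_abc_scores
from mirsense.datamodel import SubtypeProfile
from mirsense.simulate import CohortSimParams, simulate_patient_cohort


class TestWilcoxon:
    def test_exact_enumeration_toy(self):
        # all C(6,3)=20 rank splits; only one puts {4,5,6} entirely on top
        assert wilcoxon_one_sided([4, 5, 6], [1, 2, 3]) == pytest.approx(0.05)

    def test_complete_ties_give_p_one(self):
        assert wilcoxon_one_sided([1.0], [1.0]) == 1.0

    def test_wrong_direction_exceeds_half(self):
        assert wilcoxon_one_sided([1, 2, 3], [4, 5, 6]) > 0.5

    def test_empty_group_is_error(self):
        with pytest.raises(ValidationError):
            wilcoxon_one_sided([], [1.0])


class TestResponseCorrelation:
    def test_scores_equal_to_codes_give_cc_one(self):
        responses = ["CR", "CRu", "PR", "SD", "PD", "Dead"]
        scores = [5, 4, 3, 2, 1, 0]
        cc, p = response_correlation(scores, responses)
        assert cc == pytest.approx(1.0)

    def test_five_patient_hand_oracle(self):
        responses = ["Dead", "PR", "SD", "CR", "CRu"]  # codes 0,3,2,5,4
        scores = [1.0, 2.0, 3.0, 4.0, 5.0]
        cc, p = response_correlation(scores, responses)
        # product-moment by hand: sum xc*yc = 10, sum xc^2 = 10, sum yc^2 = 14.8
        expected = 10.0 / np.sqrt(10.0 * 14.8)
        assert cc == pytest.approx(expected, abs=1e-12)

    def test_unevaluable_patients_excluded(self):
        responses = ["CR", "CRu", "PR", "Unevaluable"]
        scores = [3.0, 2.0, 1.0, -999.0]  # outlier must not matter
        cc, _ = response_correlation(scores, responses)
        assert cc == pytest.approx(1.0)

    def test_dead_exclusion_flag(self):
        coding = ResponseCoding(include_dead=False)
        responses = ["CR", "CRu", "PR", "Dead"]
        scores = [3.0, 2.0, 1.0, 50.0]
        cc, _ = response_correlation(scores, responses, coding)
        assert cc == pytest.approx(1.0)


class TestKaplanMeier:
    def test_all_events_median(self):
        curve = km_curve([100, 200, 300], [1, 1, 1])
        median, _ = median_survival(curve)
        assert median == 200

    def test_all_censored_median_not_reached(self):
        curve = km_curve([100, 200, 300], [0, 0, 0])
        median, _ = median_survival(curve)
        assert np.isinf(median)

    def test_six_subject_product_limit_by_hand(self):
        curve = km_curve([1, 2, 2, 3, 4, 5], [1, 1, 0, 1, 0, 1])
        assert curve.survival_at(1) == pytest.approx(5 / 6, abs=1e-12)
        assert curve.survival_at(2) == pytest.approx(2 / 3, abs=1e-12)
        assert curve.survival_at(3) == pytest.approx(4 / 9, abs=1e-12)
        assert curve.survival_at(5) == pytest.approx(0.0, abs=1e-12)
        median, (lo, hi) = median_survival(curve)
        assert median == 3.0
        assert lo <= median <= hi or np.isinf(hi)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(100, size=40)
        curve = km_curve(t, np.ones(40, dtype=bool))
        for q in np.quantile(t, [0.1, 0.5, 0.9]):
            assert curve.survival_at(q) == pytest.approx((t > q).mean(), abs=1e-12)

    def test_survival_monotone_from_one(self):
        curve = km_curve([5, 3, 8, 1], [1, 0, 1, 1])
        assert curve.survival[0] == 1.0
        assert (np.diff(curve.survival) <= 1e-12).all()


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([10.0, 20, 30]); e = np.array([1, 0, 1], dtype=bool)
        stat, p = logrank([(t, e), (t, e)])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_four_subject_hand_calculation(self):
        # observed-minus-expected by hand gives chi-square 8/13
        stat, p = logrank(
            [(np.array([1, 3]), np.array([1, 1], bool)),
             (np.array([2, 4]), np.array([1, 1], bool))]
        )
        assert stat == pytest.approx(8 / 13, abs=1e-9)
        assert p == pytest.approx(stats.chi2.sf(8 / 13, 1), abs=1e-9)

    def test_group_label_swap_invariance(self):
        rng = np.random.default_rng(4)
        g1 = (rng.exponential(1, 20), rng.random(20) < 0.8)
        g2 = (rng.exponential(2, 25), rng.random(25) < 0.8)
        assert logrank([g1, g2])[0] == pytest.approx(logrank([g2, g1])[0], abs=1e-12)

    def test_empty_group_is_error(self):
        with pytest.raises(ValidationError):
            logrank([(np.array([1.0]), np.array([True])), (np.array([]), np.array([]))])


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([10, 9, 8, 1, 2], [1, 1, 1, 0, 0])
        assert auc == 1.0

    def test_pair_counting_toy(self):
        # responders {3,1}, non-responders {2,0}: 3 of 4 pairs concordant
        _, auc = roc_auc([3, 1, 2, 0], [1, 1, 0, 0])
        assert auc == 0.75

    def test_chance_level_for_independent_scores(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=4000)
        labels = rng.random(4000) < 0.5
        _, auc = roc_auc(scores, labels)
        assert abs(auc - 0.5) < 0.03

    def test_equals_mann_whitney_concordance_with_ties(self):
        rng = np.random.default_rng(9)
        scores = rng.integers(0, 5, size=60).astype(float)
        labels = rng.random(60) < 0.4
        _, auc = roc_auc(scores, labels)
        pos, neg = scores[labels], scores[~labels]
        u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
        assert auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_single_class_is_error(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestMultivariateRemissionFit:
    def test_recovers_coefficients_at_large_n(self):
        rng = np.random.default_rng(10)
        n = 5000
        pred = rng.uniform(0, 100, n)
        ipi = rng.integers(0, 6, n).astype(float)
        lin = 0.8 + 0.02 * pred - 0.4 * ipi
        y = rng.random(n) < 1 / (1 + np.exp(-lin))
        fit = multivariate_remission_fit(pred, ipi, y.astype(float))
        assert fit.params["prediction"] == pytest.approx(0.02, rel=0.25)
        assert fit.params["ipi"] == pytest.approx(-0.4, rel=0.25)
        assert fit.one_sided_p["prediction"] < 0.01
        assert fit.one_sided_p["ipi"] < 0.01
        assert not fit.separation_flagged

    def test_constant_ipi_reported_inestimable(self):
        rng = np.random.default_rng(11)
        pred = rng.uniform(0, 100, 100)
        y = (rng.random(100) < 0.7).astype(float)
        fit = multivariate_remission_fit(pred, np.full(100, 2.0), y)
        assert np.isnan(fit.params["ipi"])
        assert any("ipi" in note for note in fit.notes)

    def test_complete_separation_flagged_with_finite_fallback(self):
        pred = np.arange(40, dtype=float)
        ipi = np.tile([0.0, 1, 2, 3], 10)
        y = (pred > 19.5).astype(float)
        fit = multivariate_remission_fit(pred, ipi, y)
        assert fit.separation_flagged
        assert np.isfinite(fit.params["prediction"])
        assert np.isfinite(fit.bse["prediction"])

    def test_one_sided_p_direction(self):
        rng = np.random.default_rng(12)
        n = 800
        pred = rng.uniform(0, 100, n)
        ipi = rng.integers(0, 6, n).astype(float)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.5 + 0.03 * pred)))).astype(float)
        fit = multivariate_remission_fit(pred, ipi, y)
        # prediction truly helps: small p; IPI is null: p not tiny
        assert fit.one_sided_p["prediction"] < 0.01
        assert fit.one_sided_p["ipi"] > 0.001


def _cohort_scores(seed=0, **kw):
    from mirsense import ResponseSignature

    params = CohortSimParams(seed=seed, **kw)
    expr, records, truth = simulate_patient_cohort(params)
    sig = ResponseSignature("CHOP", tuple((f, 0.5) for f in truth.planted_features))
    sigs = {t: sig for t in {r.treatment for r in records}}
    scores = score_cohort(expr, records, sigs)
    gcb = gcb_abc_scores(
        expr, SubtypeProfile(truth.gcb_features, truth.abc_features)
    )
    return records, scores, gcb


class TestSummaryTable:
    def test_dimensions_always_3x4(self):
        records, scores, gcb = _cohort_scores(seed=1)
        table = summary_table(records, scores, gcb)
        assert table.shape == (3, 4)
        assert list(table.index) == [
            "Remission", "Overall survival", "Progression-free survival",
        ]
        assert list(table.columns) == ["Prediction", "IPI", "Combined", "GCB/ABC"]

    def test_combined_beats_prediction_on_remission_in_most_seeds(self):
        wins = 0
        for seed in range(9):
            records, scores, gcb = _cohort_scores(seed=seed)
            table = summary_table(records, scores, gcb)
            wins += (
                table.loc["Remission", "Combined"]
                <= table.loc["Remission", "Prediction"]
            )
        assert wins > 4

    def test_null_cohort_rarely_significant(self):
        null_kw = dict(
            a1=0.0, a2=0.0, ipi_log_hr=0.0, nonresponder_log_hr=0.0,
            gcb_log_hr=0.0, prog_ipi_log_hr=0.0, prog_nonresponder_log_hr=0.0,
        )
        cells = []
        for seed in range(8):
            records, scores, gcb = _cohort_scores(seed=100 + seed, **null_kw)
            table = summary_table(records, scores, gcb)
            cells.extend(table.to_numpy().ravel())
        cells = np.asarray(cells, dtype=float)
        cells = cells[~np.isnan(cells)]
        assert (cells < 0.05).mean() < 0.15
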