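"""Correlation, agreement and calibration statistics against independent oracles."""

import math
from itertools import permutations

import numpy as np
import pytest
from scipy import stats as sps

from renalmorph import (
    CohortSpec,
    correlate,
    correlation_p,
    fit_collagen_line,
    percent_agreement,
    simulate_cohort,
    validation_report,
    cohort_to_table,
)
from renalmorph.errors import SchemaError, SingularFitError, UndefinedCorrelationError


def exhaustive_permutation_p(x, y):
    """Two-sided permutation p-value of Pearson r over all orderings of y."""
    x = np.asarray(x, float)
    r_obs = abs(np.corrcoef(x, y)[0, 1])
    hits = total = 0
    for perm in permutations(y):
        hits += abs(np.corrcoef(x, perm)[0, 1]) >= r_obs - 1e-12
        total += 1
    return hits / total


class TestCorrelate:
    def test_identity_gives_unit_correlation(self):
        res = correlate([1.0, 2.5, 4.0, 8.0], [1.0, 2.5, 4.0, 8.0])
        assert res.r == pytest.approx(1.0)
        assert res.r_s == pytest.approx(1.0)
        assert res.p_r == 0.0

    def test_r_08_at_n30_is_highly_significant(self):
        assert correlation_p(0.8, 30) < 0.01

    def test_p_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=25)
        y = x + rng.normal(size=25)
        res = correlate(x, y)
        ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_r == pytest.approx(ref.pvalue, rel=1e-9)

    def test_spearman_matches_scipy_with_ties(self):
        x = [1, 2, 2, 3, 5, 8, 8]
        y = [2, 1, 4, 4, 6, 9, 10]
        res = correlate(x, y)
        ref = sps.spearmanr(x, y)
        assert res.r_s == pytest.approx(ref.statistic, rel=1e-12)

    @pytest.mark.parametrize(
        "x,y",
        [
            ([1, 2, 3, 4, 5, 6], [2, 1, 4, 3, 6, 5]),
            ([1, 2, 3, 4, 5, 6], [1, 3, 2, 5, 4, 6]),
            ([1, 5, 2, 4, 3, 6], [2, 4, 1, 5, 3, 6]),
            ([1, 2, 3, 4, 5, 6, 7], [2, 1, 3, 5, 4, 7, 6]),
        ],
    )
    def test_t_transform_matches_permutation_oracle_at_n6_n7(self, x, y):
        res = correlate(x, y)
        assert abs(res.p_r - exhaustive_permutation_p(x, y)) <= 0.02

    @pytest.mark.parametrize("n,bound", [(4, 0.16), (5, 0.09), (6, 0.06), (7, 0.04)])
    def test_small_n_discrepancy_bounded_by_permutation_granularity(self, n, bound):
        # the t approximation drifts from the exact (coarse) permutation law
        # as n shrinks; the drift stays within these characterized bounds
        rng = np.random.default_rng(n)
        worst = 0.0
        for _ in range(20):
            x = rng.permutation(n) + 1.0
            y = rng.permutation(n) + 1.0
            res = correlate(x, y)
            worst = max(worst, abs(res.p_r - exhaustive_permutation_p(x, y)))
        assert worst <= bound

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        base = correlate(x, y)
        warped = correlate(np.exp(x), y**3)
        assert warped.r_s == pytest.approx(base.r_s, abs=1e-12)

    def test_pearson_invariant_under_positive_affine_transform(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        base = correlate(x, y)
        moved = correlate(3.0 * x + 7.0, 0.5 * y - 2.0)
        assert moved.r == pytest.approx(base.r, abs=1e-12)

    @pytest.mark.parametrize(
        "x,y,err",
        [
            ([1, 1, 1, 1], [1, 2, 3, 4], UndefinedCorrelationError),
            ([1, 2, 3], [1, 2], UndefinedCorrelationError),
            ([1, 2], [1, 2], UndefinedCorrelationError),
        ],
    )
    def test_invalid_inputs_rejected(self, x, y, err):
        with pytest.raises(err):
            correlate(x, y)


class TestPercentAgreement:
    def test_identity(self):
        res = percent_agreement([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert res.mean_pct == pytest.approx(100.0)
        assert res.sem_pct == 0.0
        assert res.p_diff == 1.0

    def test_constant_86_percent_ratio(self):
        measured = np.array([50.0, 60.0, 70.0, 80.0])
        res = percent_agreement(0.86 * measured, measured)
        assert res.mean_pct == pytest.approx(86.0)
        assert res.sem_pct == pytest.approx(0.0, abs=1e-9)

    def test_scalar_ratio_property(self):
        v = np.array([10.0, 25.0, 40.0])
        res = percent_agreement(1.7 * v, v)
        assert res.mean_pct == pytest.approx(170.0)
        assert res.sem_pct == pytest.approx(0.0, abs=1e-9)

    def test_matches_direct_formula_on_random_cohort(self):
        rng = np.random.default_rng(4)
        measured = rng.uniform(40, 80, size=30)
        calculated = measured * rng.normal(1.0, 0.05, size=30)
        res = percent_agreement(calculated, measured)
        ratios = 100 * calculated / measured
        assert res.mean_pct == pytest.approx(ratios.mean())
        assert res.sem_pct == pytest.approx(ratios.std(ddof=1) / math.sqrt(30))
        assert res.p_diff == pytest.approx(sps.ttest_1samp(ratios, 100.0).pvalue)

    def test_paired_mode_matches_scipy(self):
        rng = np.random.default_rng(5)
        measured = rng.uniform(40, 80, size=20)
        calculated = measured + rng.normal(0, 2, size=20)
        res = percent_agreement(calculated, measured, mode="paired")
        assert res.p_diff == pytest.approx(sps.ttest_rel(calculated, measured).pvalue)

    def test_zero_measured_rejected(self):
        with pytest.raises(SchemaError):
            percent_agreement([1.0, 2.0], [1.0, 0.0])


class TestCalibrationFit:
    def test_exact_line_recovered_from_collinear_points(self):
        x = [0.0, 50.0, 100.0]
        y = [7.7 * xi - 188.5 for xi in x]
        model, diag = fit_collagen_line(x, y)
        assert model.slope == pytest.approx(7.7, abs=1e-10)
        assert model.intercept == pytest.approx(-188.5, abs=1e-8)
        assert diag.r_squared == pytest.approx(1.0)

    def test_noise_free_cohort_recovery_to_float_precision(self, noise_free_spec):
        recs = simulate_cohort(noise_free_spec)
        model, _ = fit_collagen_line(
            [r.areas.A_e for r in recs], [r.collagen_true for r in recs]
        )
        assert model.slope == pytest.approx(7.7, rel=1e-9)
        assert model.intercept == pytest.approx(-188.5, rel=1e-9)

    def test_ols_residual_identities(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(30, 90, size=28)
        y = 7.7 * x - 188.5 + rng.normal(0, 40, size=28)
        model, _ = fit_collagen_line(x, y)
        resid = y - (model.slope * x + model.intercept)
        assert resid.sum() == pytest.approx(0.0, abs=1e-8)
        assert (resid * x).sum() == pytest.approx(0.0, abs=1e-6)

    def test_singular_and_undersized_fits_rejected(self):
        with pytest.raises(SingularFitError):
            fit_collagen_line([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])
        with pytest.raises(SingularFitError):
            fit_collagen_line([0.0, 100.0], [-188.5, 581.5])


class TestValidationReport:
    def test_noise_free_cohort_reports_unit_correlation(self, noise_free_spec):
        table = cohort_to_table(simulate_cohort(noise_free_spec))
        report, summary = validation_report(table)
        row = report.set_index("comparison").loc["collagen_vs_Ae"]
        assert row["r"] == pytest.approx(1.0, abs=1e-12)
        assert "collagen_vs_Ae" in summary

    def test_default_cohort_report_is_well_formed(self):
        table = cohort_to_table(simulate_cohort(CohortSpec(seed=9)))
        report, _ = validation_report(table)
        assert set(report["comparison"]) == {
            "A_vs_Am", "Ae_vs_Am", "collagen_vs_Am", "collagen_vs_Ae",
        }
        assert ((report["p_r"] >= 0) & (report["p_r"] <= 1)).all()
        agree = report.set_index("comparison").loc["A_vs_Am"]
        assert agree["mean_pct"] < 100  # standard formula underestimates

    def test_missing_columns_rejected(self):
        import pandas as pd

        with pytest.raises(SchemaError):
            validation_report(pd.DataFrame({"A_mm2": [1, 2, 3]}))
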