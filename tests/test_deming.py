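import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neqsel import DemingRegression, agreement_stats, validate
from neqsel.exceptions import ContractError, DegenerateFitError, InsufficientDataError


def orthogonal_deming_slope(x, y):
    """Closed-form lambda=1 (equal-variance) Deming slope."""
    x, y = np.asarray(x), np.asarray(y)
    sxx = np.var(x, ddof=1)
    syy = np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    return (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy**2)) / (2 * sxy)


class TestDemingFit:
    def test_identity_line_recovered(self):
        x = np.array([-4.0, -1.0, 0.5, 2.0, 6.0])
        res = DemingRegression(x, x, y_se=0.3, x_se=0.3).fit()
        assert res.slope == pytest.approx(1.0, abs=1e-8)
        assert res.intercept == pytest.approx(0.0, abs=1e-8)

    def test_noiseless_affine_line(self):
        x = np.array([-3.0, 0.0, 1.0, 4.0, 9.0])
        y = 2.0 * x + 1.0
        res = DemingRegression(y, x, y_se=0.8, x_se=0.2).fit()
        assert res.slope == pytest.approx(2.0, abs=1e-8)
        assert res.intercept == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_orthogonal_closed_form(self, seed):
        """Equal constant SEs on both axes reduce to orthogonal regression."""
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 3, 15)
        y = 1.4 * x - 0.5 + rng.normal(0, 1.0, 15)
        res = DemingRegression(y, x, y_se=0.7, x_se=0.7).fit()
        assert res.slope == pytest.approx(orthogonal_deming_slope(x, y), abs=1e-8)

    def test_ols_limit_as_x_se_vanishes(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0, 2, 30)
        y = 0.8 * x + rng.normal(0, 0.5, 30)
        b_ols = np.polyfit(x, y, 1)[0]
        res = DemingRegression(y, x, y_se=0.5, x_se=1e-8).fit()
        assert res.slope == pytest.approx(b_ols, abs=1e-5)

    @pytest.mark.parametrize("c", [0.1, 2.0, 25.0])
    def test_scale_equivariance_in_y(self, c):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 2, 12)
        y = 1.2 * x + rng.normal(0, 0.4, 12)
        base = DemingRegression(y, x, y_se=0.4, x_se=0.4).fit()
        scaled = DemingRegression(c * y, x, y_se=c * 0.4, x_se=0.4).fit()
        assert scaled.slope == pytest.approx(c * base.slope, rel=1e-6)

    def test_axis_swap_inverts_slope(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 2, 20)
        y = 2.5 * x + rng.normal(0, 0.3, 20)
        fwd = DemingRegression(y, x, y_se=0.5, x_se=0.5).fit()
        rev = DemingRegression(x, y, y_se=0.5, x_se=0.5).fit()
        assert rev.slope == pytest.approx(1.0 / fwd.slope, rel=1e-6)

    def test_zero_se_points_get_smallest_positive(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.1, 0.9, 2.2, 2.9])
        res = DemingRegression(y, x, y_se=[0.0, 0.5, 0.5, 0.5], x_se=0.2).fit()
        ref = DemingRegression(y, x, y_se=[0.5, 0.5, 0.5, 0.5], x_se=0.2).fit()
        assert res.slope == pytest.approx(ref.slope, rel=1e-9)

    def test_ci_contains_slope_and_flags_significance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 3, 12)
        y = x + rng.normal(0, 0.5, 12)
        res = DemingRegression(y, x, y_se=0.5, x_se=0.5).fit()
        assert res.slope_ci_low <= res.slope <= res.slope_ci_high
        assert res.significant == (res.slope_ci_low > 0 or res.slope_ci_high < 0)

    def test_jackknife_ci_shrinks_with_n(self):
        rng = np.random.default_rng(17)

        def width(n):
            x = rng.normal(0, 3, n)
            y = x + rng.normal(0, 0.8, n)
            r = DemingRegression(y, x, y_se=0.8, x_se=0.8).fit()
            return r.slope_ci_high - r.slope_ci_low

        assert np.mean([width(80) for _ in range(5)]) < np.mean(
            [width(10) for _ in range(5)]
        )

    def test_insufficient_or_degenerate_data_rejected(self):
        with pytest.raises(InsufficientDataError):
            DemingRegression([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(DegenerateFitError):
            DemingRegression([1.0, 2.0, 3.0], [4.0, 4.0, 4.0])

    def test_summary_mentions_key_quantities(self):
        x = np.array([0.0, 1.0, 2.0, 4.0])
        res = DemingRegression(x, x, y_se=0.1, x_se=0.1, label="BAR").fit()
        text = res.summary()
        assert "slope" in text and "R^2" in text and "BAR" in text


class TestAgreementStats:
    def test_perfect_identity(self):
        x = np.array([0.0, 1.0, 2.0])
        r2, rmse, mae = agreement_stats(x, x)
        assert (r2, rmse, mae) == (pytest.approx(1.0), pytest.approx(0.0), pytest.approx(0.0))

    def test_sign_flip_keeps_r2(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        r2, rmse, _ = agreement_stats(x, -x)
        assert r2 == pytest.approx(1.0)
        assert rmse == pytest.approx(np.sqrt(np.mean((2 * x) ** 2)))

    def test_hand_computed_correlation(self):
        r2, _, _ = agreement_stats([0.0, 1.0, 2.0], [0.0, 1.0, 5.0])
        assert np.sqrt(r2) == pytest.approx(0.9449, abs=1e-4)
        assert r2 == pytest.approx(0.8929, abs=1e-4)

    def test_zero_variance_reports_nan_r2(self):
        r2, rmse, mae = agreement_stats([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])
        assert np.isnan(r2)
        assert rmse > 0 and mae > 0

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10**6))
    def test_rmse_dominates_mae(self, seed):
        """Power-mean inequality: rmse >= mae on every input."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 30))
        x = rng.normal(0, 5, n)
        y = x + rng.normal(0, rng.uniform(0.1, 5), n)
        _, rmse, mae = agreement_stats(x, y)
        assert rmse >= mae - 1e-12


class TestValidate:
    def _tables(self, slope=1.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        cells = [(a, t) for a in ("2", "3", "4") for t in ("CDK1", "CDK2", "CDK5", "CDK9")]
        x_by_cell = {cell: rng.normal(0, 3) for cell in cells}
        rows_e = [
            {"compound_i": a, "compound_j": "1", "target": t, "ddg": x, "se": 0.3}
            for (a, t), x in x_by_cell.items()
        ]
        rows_c = [
            {
                "compound_i": a,
                "compound_j": "1",
                "target": t,
                "method": method,
                "ddg": slope * x + noise * rng.normal(),
                "se": 0.4,
            }
            for method in ("JAR", "CGI", "BAR")
            for (a, t), x in x_by_cell.items()
        ]
        return pd.DataFrame(rows_c), pd.DataFrame(rows_e)

    def test_per_method_results_on_panel_geometry(self):
        calc, exp = self._tables(noise=0.2, seed=1)
        results, points, diag = validate(calc, exp)
        assert set(results) == {"JAR", "CGI", "BAR"}
        assert all(r.n == 12 for r in results.values())
        assert len(points) == 36

    def test_identical_tables_give_identity_fit(self):
        calc, exp = self._tables(noise=0.0, seed=2)
        # use the experimental x as the calculated value too
        results, _, _ = validate(calc, exp)
        for res in results.values():
            assert res.slope == pytest.approx(1.0, abs=1e-6)
            assert res.r2 == pytest.approx(1.0, abs=1e-9)
            assert res.significant

    def test_unmatched_rows_diagnosed(self):
        calc, exp = self._tables()
        calc = calc[~((calc["compound_i"] == "2") & (calc["target"] == "CDK1"))]
        results, _, diag = validate(calc, exp)
        assert any("unmatched" in d for d in diag)

    def test_empty_join_rejected(self):
        calc, exp = self._tables()
        exp = exp.assign(target="CDK7")
        with pytest.raises(ContractError):
            validate(calc, exp)

    def test_slope_ci_coverage_on_synthetic_studies(self):
        """The jackknife slope CI covers the true slope 1 in >= 90% of 50
        seeded synthetic studies run through the full pipeline."""
        from neqsel import RunConfig, SelectivityStudy, SyntheticStudySpec

        covered = 0
        n_runs = 50
        for seed in range(n_runs):
            spec = SyntheticStudySpec(
                n_forward=60, n_reverse=60, work_sigma=2.0, ic50_noise_sd=0.1, seed=seed
            )
            cfg = RunConfig(seed=seed, methods=("BAR",), n_boot=30)
            res = SelectivityStudy.from_synthetic(spec, cfg).fit()
            r = res.ddg_validation["BAR"]
            covered += r.slope_ci_low <= 1.0 <= r.slope_ci_high
        assert covered / n_runs >= 0.9
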