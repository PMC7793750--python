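"""Identity-link Poisson ML fitting of the linear-quadratic curve."""

import numpy as np
import pytest
from scipy import optimize, stats

from dcacalib import (
    CalibrationCurve,
    DegenerateFitError,
    InvalidCountData,
    curve_confidence_band,
    fit_lq,
    goodness_of_fit,
    predict_yield,
    table_from_arrays,
)


def _aggregate_loglik(table, coef):
    n, x, d = table.cells.astype(float), table.dicentrics.astype(float), table.doses
    yhat = coef[0] + coef[1] * d + coef[2] * d**2
    if np.any(yhat <= 0):
        return -np.inf
    return float(np.sum(np.where(x > 0, x * np.log(n * yhat), 0.0) - n * yhat))


def _pack_multiplicities(n, x, kmax=5):
    """Distribute x dicentrics over n cells (aggregate fits only use X, N)."""
    full, rem = divmod(int(x), kmax)
    mult = [0] * (kmax + 1)
    mult[kmax] = full
    if rem:
        mult[rem] += 1
    mult[0] = int(n) - sum(mult[1:])
    return tuple(mult)


class TestFitReferenceTables:
    def test_assisted_fit_frozen_coefficients(self, table1):
        """Regression: the ML optimum on the assisted table (full precision)."""
        curve = fit_lq(table1)
        assert curve.c == pytest.approx(0.0020374, abs=2e-6)
        assert curve.alpha == pytest.approx(0.0366096, abs=2e-6)
        assert curve.beta == pytest.approx(0.0687258, abs=2e-6)
        assert curve.se_c == pytest.approx(2.191e-4, rel=1e-3)
        assert curve.se_alpha == pytest.approx(1.8628e-3, rel=1e-3)
        assert curve.se_beta == pytest.approx(8.550e-4, rel=1e-3)

    def test_assisted_ses_match_published_at_printed_precision(self, table1):
        curve = fit_lq(table1)
        for se, printed in [
            (curve.se_c, 0.0002),
            (curve.se_alpha, 0.0019),
            (curve.se_beta, 0.0009),
        ]:
            assert abs(se - printed) <= 5.1e-5

    def test_automated_fit_and_lack_of_fit(self, table2):
        curve = fit_lq(table2)
        assert curve.c == pytest.approx(0.0622, abs=2e-4)
        diag = goodness_of_fit(curve, table2)
        assert diag.pearson_chi2 == pytest.approx(97.9, abs=0.1)
        assert diag.dof == 7
        assert diag.p_value < 1e-4

    def test_automated_dispersion_scaled_ses_match_published(self, table2):
        """The published automated-curve SEs equal Poisson SEs x sqrt(chi2/dof)."""
        curve = fit_lq(table2, dispersion_scale=True)
        assert abs(curve.se_c - 0.0035) <= 1.1e-4
        assert abs(curve.se_alpha - 0.0104) <= 1.1e-4
        assert abs(curve.se_beta - 0.0031) <= 1.1e-4

    def test_coefficient_z_tests_highly_significant(self, table1):
        diag = goodness_of_fit(fit_lq(table1), table1)
        assert all(p < 1e-4 for p in diag.coef_p.values())


class TestFitCorrectness:
    def test_matches_generic_numerical_maximizer(self, table1, table2):
        """Independent check: scipy maximizes the same log-likelihood."""
        for table in (table1, table2):
            curve = fit_lq(table)
            res = optimize.minimize(
                lambda p: -_aggregate_loglik(table, p),
                x0=[0.01, 0.05, 0.05],
                method="Nelder-Mead",
                options=dict(xatol=1e-12, fatol=1e-12, maxiter=20000),
            )
            assert np.allclose(curve.coefficients, res.x, atol=1e-6)

    def test_matches_statsmodels_glm(self, table1):
        """Cross-check against identity-link Poisson GLM (N-scaled design)."""
        sm = pytest.importorskip("statsmodels.api")
        import warnings

        d, n, x = table1.doses, table1.cells.astype(float), table1.dicentrics
        design = np.column_stack([n, n * d, n * d**2])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fam = sm.families.Poisson(sm.families.links.Identity())
            res = sm.GLM(x, design, family=fam).fit()
        curve = fit_lq(table1)
        assert np.allclose(curve.coefficients, res.params, atol=1e-8)
        # SEs differ slightly: observed vs expected Fisher information
        assert np.allclose(
            [curve.se_c, curve.se_alpha, curve.se_beta], res.bse, rtol=1e-2
        )

    def test_noiseless_forward_construction_recovered(self):
        """Counts built exactly from a known curve return that curve."""
        c, a, b = 0.002, 0.03, 0.07
        doses = np.arange(0.0, 6.0)
        n = np.full(doses.size, 10**6)
        x = np.round(n * (c + a * doses + b * doses**2)).astype(int)
        mult = [_pack_multiplicities(nn, xx) for nn, xx in zip(n, x)]
        table = table_from_arrays(doses, n, mult)
        curve = fit_lq(table)
        assert curve.c == pytest.approx(c, rel=5e-4)
        assert curve.alpha == pytest.approx(a, rel=5e-4)
        assert curve.beta == pytest.approx(b, rel=5e-4)

    def test_scale_equivariance(self, table1):
        """Scaling all counts by m keeps coefficients, shrinks SEs by sqrt(m)."""
        m = 4
        scaled = table_from_arrays(
            table1.doses,
            table1.cells * m,
            [tuple(m * d for d in r.multiplicity_counts) for r in table1.rows],
        )
        c1, c2 = fit_lq(table1), fit_lq(scaled)
        assert np.allclose(c1.coefficients, c2.coefficients, rtol=1e-8)
        assert np.allclose(
            [c1.se_c, c1.se_alpha, c1.se_beta],
            [v * np.sqrt(m) for v in (c2.se_c, c2.se_alpha, c2.se_beta)],
            rtol=1e-6,
        )

    def test_nonnegativity_projection(self):
        """A concave yield trend drives beta negative; it is projected to 0."""
        doses = np.array([0.5, 1.0, 2.0, 3.0, 4.0])
        n = np.full(5, 10**5)
        y = 0.05 * np.sqrt(doses)  # concave: LQ beta would be negative
        x = np.round(n * y).astype(int)
        table = table_from_arrays(doses, n, [(nn - xx, xx) for nn, xx in zip(n, x)])
        curve = fit_lq(table)
        assert curve.beta == 0.0
        assert curve.n_free_parameters == 2
        assert curve.alpha > 0

    def test_input_validation(self, table1):
        with pytest.raises(InvalidCountData, match="at least 3"):
            fit_lq(table_from_arrays([0, 1], [10, 10], [(9, 1), (8, 2)]))
        with pytest.raises(InvalidCountData, match="no dicentrics"):
            fit_lq(table_from_arrays([0, 1, 2], [5, 5, 5], [(5,), (5,), (5,)]))
        with pytest.raises(InvalidCountData, match="order"):
            fit_lq(table1, order="cubic")


class TestPrediction:
    def test_predict_published_coefficients(self, published_assisted_curve):
        c = published_assisted_curve
        assert predict_yield(c, 0) == pytest.approx(0.0020)
        # sum of the printed coefficients; observed yield at 1 Gy was 0.108
        assert predict_yield(c, 1) == pytest.approx(0.1078)
        assert predict_yield(c, 5) == pytest.approx(1.9090)

    def test_predict_rejects_negative_dose(self, published_assisted_curve):
        with pytest.raises(InvalidCountData):
            predict_yield(published_assisted_curve, -1.0)


class TestGoodnessOfFit:
    def test_perfect_fit_gives_zero_chi2(self):
        c, a, b = 0.01, 0.1, 0.05
        doses = np.array([0.0, 1.0, 2.0, 3.0])
        n = np.full(4, 1000)
        x = np.round(n * (c + a * doses + b * doses**2)).astype(int)
        table = table_from_arrays(doses, n, [(nn - xx, xx) for nn, xx in zip(n, x)])
        curve = CalibrationCurve.from_coefficients(c, a, b)
        diag = goodness_of_fit(curve, table)
        assert diag.pearson_chi2 == pytest.approx(0.0, abs=1e-12)
        assert diag.dof == 1

    def test_degenerate_curve_rejected(self, table1):
        flat = CalibrationCurve.from_coefficients(0.0, 0.1, 0.0)
        with pytest.raises(DegenerateFitError):
            goodness_of_fit(flat, table1)  # zero yield predicted at 0 Gy


class TestConfidenceBand:
    def test_zero_covariance_collapses_to_curve(self, published_assisted_curve):
        c = CalibrationCurve.from_coefficients(0.002, 0.04, 0.07)
        doses = [0.0, 1.0, 5.0]
        lo, hi = curve_confidence_band(c, doses)
        assert np.allclose(lo, hi)
        assert np.allclose(lo, [predict_yield(c, d) for d in doses])

    def test_band_at_zero_dose_is_intercept_se(self, table1):
        curve = fit_lq(table1)
        lo, hi = curve_confidence_band(curve, [0.0])
        z = stats.norm.ppf(0.975)
        assert hi[0] - lo[0] == pytest.approx(2 * z * curve.se_c, rel=1e-9)

    def test_band_against_monte_carlo_oracle(self, table1):
        """Delta band matches percentile band of MVN coefficient draws (2%)."""
        curve = fit_lq(table1)
        rng = np.random.default_rng(7)
        draws = rng.multivariate_normal(curve.coefficients, curve.covariance, 10**5)
        d = 1.0
        sims = draws[:, 0] + draws[:, 1] * d + draws[:, 2] * d**2
        mc_lo, mc_hi = np.percentile(sims, [2.5, 97.5])
        lo, hi = curve_confidence_band(curve, [d])
        width = hi[0] - lo[0]
        assert width == pytest.approx(mc_hi - mc_lo, rel=0.02)

    def test_band_with_poisson_term_covers_all_observations(self, table1):
        """With per-dose Poisson error added, all 10 observed yields are
        inside the 95% band (as the reference study reports); the pure
        coefficient-covariance band is narrower and excludes two points."""
        curve = fit_lq(table1)
        lo, hi = curve_confidence_band(curve, table1.doses, cells=table1.cells)
        y = table1.yields
        assert np.all((lo <= y) & (y <= hi))
        lo2, hi2 = curve_confidence_band(curve, table1.doses)
        assert int(np.sum((lo2 <= y) & (y <= hi2))) == 8

    def test_missing_covariance_raises(self):
        bare = CalibrationCurve(0.002, 0.04, 0.07)
        with pytest.raises(Exception, match="covariance"):
            curve_confidence_band(bare, [1.0])
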