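"""Posterior summaries, contrasts, prediction intervals, R², PSIS-LOO."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import logsumexp

from hrvent import analysis
from hrvent.analysis import (
    LooResult,
    bayes_r2,
    compare_elpd,
    contrast,
    domain_intercepts,
    domain_slopes,
    pointwise_loglik,
    prediction_interval,
    psis_loo,
    summarize,
)
from hrvent.models import (
    COL_DOMAIN,
    COL_HR,
    COL_SUBJECT,
    COL_VE,
    InvalidParameterError,
    ModelForm,
    PosteriorDraws,
)

from conftest import (
    TABLE_EXP_BETA,
    TABLE_EXP_SIGMA,
    TABLE_LINEAR_BETA,
    TABLE_LINEAR_SIGMA,
    degenerate_draws,
    toy_dataset,
)


class TestSummarize:
    def test_three_draws_linear_interpolated_percentiles(self):
        s = summarize(np.array([1.0, 2.0, 3.0]))
        assert s.median == 2.0
        assert s.lower == pytest.approx(1.05)
        assert s.upper == pytest.approx(2.95)

    def test_constant_draws(self):
        s = summarize(np.full(500, 3.3))
        assert s.median == s.lower == s.upper == 3.3

    def test_symmetric_draws(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(20000)
        x = np.concatenate([x, -x])  # exactly symmetric
        s = summarize(x)
        assert s.median == pytest.approx(0.0, abs=1e-12)
        assert s.lower == pytest.approx(-s.upper, rel=1e-9)

    def test_unknown_quantity_rejected(self):
        d = degenerate_draws(TABLE_LINEAR_BETA, TABLE_LINEAR_SIGMA)
        with pytest.raises(KeyError):
            summarize(d, "beta7")

    def test_equal_tailed_interval_mass(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(2.0, 1.0, 4000)
        s = summarize(x)
        frac_below = np.mean(x < s.lower)
        assert abs(frac_below - 0.025) <= 1.5 / x.size * 10  # +- one draw's resolution


class TestDomainQuantities:
    def test_marginal_slopes_from_table_medians(self):
        d = degenerate_draws(TABLE_LINEAR_BETA, TABLE_LINEAR_SIGMA)
        slopes = domain_slopes(d)
        assert slopes["moderate"].median == pytest.approx(0.54)
        assert slopes["heavy"].median == pytest.approx(0.99)
        assert slopes["severe"].median == pytest.approx(1.98)

    def test_composite_intercepts_from_table_medians(self):
        d = degenerate_draws(TABLE_LINEAR_BETA, TABLE_LINEAR_SIGMA)
        ints = domain_intercepts(d)
        assert ints["moderate"].median == pytest.approx(-32.92)
        assert ints["heavy"].median == pytest.approx(-101.94)
        assert ints["severe"].median == pytest.approx(-268.81)

    def test_zero_interactions_collapse_to_common_line(self):
        d = degenerate_draws([-32.92, 0.54, 0, 0, 0, 0], 3.5)
        slopes = domain_slopes(d)
        assert slopes["moderate"].median == slopes["heavy"].median \
            == slopes["severe"].median

    def test_exponential_fit_rejected(self):
        d = degenerate_draws(TABLE_EXP_BETA, TABLE_EXP_SIGMA, form="exponential")
        with pytest.raises(InvalidParameterError):
            domain_slopes(d)
        with pytest.raises(InvalidParameterError):
            domain_intercepts(d)


class TestContrast:
    def test_identical_quantities_give_zero_and_p_zero(self):
        d = degenerate_draws(TABLE_LINEAR_BETA, TABLE_LINEAR_SIGMA)
        c = contrast(d, "slope_heavy", "slope_heavy")
        assert c.summary.median == 0.0
        assert c.p_below_zero == 0.0  # strict inequality convention

    def test_severe_vs_moderate_slope_contrast(self):
        d = degenerate_draws(TABLE_LINEAR_BETA, TABLE_LINEAR_SIGMA)
        c = contrast(d, "slope_severe", "slope_moderate")
        assert c.summary.median == pytest.approx(1.44)
        assert c.p_below_zero == 0.0

    def test_all_negative_differences(self):
        d = degenerate_draws([0.0, -1.0, 0, 0, 0, 0], 1.0)
        c = contrast(d, "slope_heavy", "intercept_moderate")  # -1 - 0
        assert c.p_below_zero == 1.0


class TestPredictionInterval:
    def test_table_sigma_values_round_to_published_halfwidths(self):
        d_lin = degenerate_draws(TABLE_LINEAR_BETA, 3.50)
        half, rounded = prediction_interval(d_lin)
        assert half == pytest.approx(6.86)
        assert rounded == 7
        d_exp = degenerate_draws(TABLE_EXP_BETA, 5.01, form="exponential")
        half, rounded = prediction_interval(d_exp)
        assert half == pytest.approx(9.8196)
        assert rounded == 10

    def test_zero_sigma(self):
        d = degenerate_draws(TABLE_LINEAR_BETA, 0.0)
        half, rounded = prediction_interval(d)
        assert half == 0.0 and rounded == 0

    def test_posterior_predictive_coverage(self):
        """New observations at fixed parameters fall inside mu +- 1.96 sigma
        95% +- 2% of the time."""
        rng = np.random.default_rng(5)
        sigma = 3.5
        n = 10_000
        mu_i = rng.uniform(20, 100, n)
        ve = mu_i + sigma * rng.standard_normal(n)
        inside = np.abs(ve - mu_i) <= 1.96 * sigma
        assert abs(inside.mean() - 0.95) <= 0.02


def _toy_draws_and_data():
    """Tiny fixed-effects draws + 3-observation dataset for R²/LOO oracles."""
    beta = np.zeros((1, 120, 2))
    beta[0, :, 0] = np.linspace(2.5, 3.5, 120)
    beta[0, :, 1] = 0.019
    draws = PosteriorDraws(
        form=ModelForm.EXPONENTIAL,
        beta=beta,
        sigma_within=np.full((1, 120), 4.0),
        sigma_b=None, corr=None, b=None, subject_ids=[],
    )
    data = pd.DataFrame({
        COL_SUBJECT: ["a", "a", "b"],
        COL_HR: [120.0, 150.0, 180.0],
        COL_VE: [28.0, 50.0, 90.0],
    })
    return draws, data


class TestBayesR2:
    def test_matches_direct_formula_oracle(self):
        draws, data = _toy_draws_and_data()
        got = bayes_r2(draws, data)
        # spreadsheet-style computation
        hr = data[COL_HR].to_numpy()
        r2 = []
        for d in range(120):
            m = draws.beta[0, d, 0] * np.exp(draws.beta[0, d, 1] * hr)
            vm = m.var()
            r2.append(vm / (vm + 16.0))
        assert got.median == pytest.approx(np.median(r2), rel=1e-12)

    def test_r2_tends_to_one_as_sigma_vanishes(self):
        draws, data = _toy_draws_and_data()
        draws.sigma_within = np.full((1, 120), 1e-9)
        assert bayes_r2(draws, data).median == pytest.approx(1.0, abs=1e-12)

    def test_constant_mu_gives_zero(self):
        draws, data = _toy_draws_and_data()
        draws.beta[0, :, 1] = 0.0  # mu constant in hr
        assert bayes_r2(draws, data).median == 0.0

    def test_degenerate_case_rejected(self):
        draws, data = _toy_draws_and_data()
        draws.beta[0, :, 1] = 0.0
        draws.sigma_within = np.zeros((1, 120))
        with pytest.raises(InvalidParameterError):
            bayes_r2(draws, data)

    def test_bounded_between_zero_and_one(self, recovery_study):
        res = recovery_study[0]
        s = bayes_r2(res["linear"], res["data"])
        assert 0.0 <= s.lower <= s.median <= s.upper <= 1.0


class TestPointwiseLoglik:
    def test_sums_to_log_likelihood_per_draw(self):
        draws, data = _toy_draws_and_data()
        ll = pointwise_loglik(draws, data)
        for d in (0, 60, 119):
            params = draws.draw_params(0, d)
            from hrvent.models import log_likelihood

            assert ll[d].sum() == pytest.approx(
                log_likelihood(params, data), rel=1e-12)

    def test_observation_at_mode_with_unit_sigma(self):
        draws, data = _toy_draws_and_data()
        draws.sigma_within = np.ones((1, 120))
        hr0 = data[COL_HR].iloc[0]
        data.loc[0, COL_VE] = draws.beta[0, 0, 0] * np.exp(0.019 * hr0)
        ll = pointwise_loglik(draws, data)
        assert ll[0, 0] == pytest.approx(-0.9189, abs=1e-4)

    def test_matches_scipy_density_oracle(self):
        draws, data = _toy_draws_and_data()
        ll = pointwise_loglik(draws, data)
        m = draws.beta[0, 7, 0] * np.exp(0.019 * data[COL_HR].to_numpy())
        expected = stats.norm.logpdf(data[COL_VE].to_numpy(), m, 4.0)
        assert np.allclose(ll[7], expected, rtol=1e-12)

    def test_unknown_subject_rejected(self, recovery_study):
        res = recovery_study[0]
        bad = res["data"].copy()
        bad.loc[0, COL_SUBJECT] = "GHOST"
        with pytest.raises(InvalidParameterError):
            pointwise_loglik(res["linear"], bad)


class TestPsisLoo:
    def test_pointwise_dominance_implies_elpd_order(self):
        rng = np.random.default_rng(0)
        ll_b = rng.normal(-3.0, 0.3, size=(400, 12))
        ll_a = ll_b + 0.5  # uniformly better
        assert psis_loo(ll_a).elpd >= psis_loo(ll_b).elpd

    def test_identical_matrices_give_zero_difference(self):
        rng = np.random.default_rng(1)
        ll = rng.normal(-3.0, 0.5, size=(300, 10))
        c = compare_elpd(psis_loo(ll), psis_loo(ll))
        assert c.elpd_diff == 0.0 and c.se_diff == 0.0

    def test_nonfinite_loglik_rejected(self):
        ll = np.full((200, 5), -1.0)
        ll[0, 0] = -np.inf
        with pytest.raises(InvalidParameterError):
            psis_loo(ll)

    def test_matches_analytic_loo_on_conjugate_normal_mean(self):
        """Known-sigma normal mean with conjugate prior: PSIS-LOO equals the
        closed-form leave-one-out predictive density within MC error."""
        rng = np.random.default_rng(7)
        sigma, tau, n = 1.0, 10.0, 20
        y = rng.normal(0.7, sigma, n)

        def posterior(y_sub):
            prec = 1 / tau**2 + len(y_sub) / sigma**2
            return (y_sub.sum() / sigma**2) / prec, 1.0 / prec

        # exact LOO
        exact = 0.0
        for i in range(n):
            y_i = np.delete(y, i)
            m, v = posterior(y_i)
            exact += stats.norm.logpdf(y[i], m, np.sqrt(v + sigma**2))
        # PSIS-LOO from posterior draws
        m, v = posterior(y)
        theta = rng.normal(m, np.sqrt(v), 8000)
        ll = stats.norm.logpdf(y[None, :], theta[:, None], sigma)
        got = psis_loo(ll)
        assert got.elpd == pytest.approx(exact, abs=0.25)
        assert np.all(got.pareto_k < 0.7)

    def test_loo_invariants(self):
        rng = np.random.default_rng(2)
        ll = rng.normal(-2.5, 0.4, size=(500, 30))
        res = psis_loo(ll)
        assert res.elpd == pytest.approx(res.pointwise.sum(), rel=1e-12)
        assert res.se == pytest.approx(
            np.sqrt(30 * np.var(res.pointwise, ddof=1)), rel=1e-12)


class TestCompareElpd:
    def test_constant_pointwise_difference(self):
        rng = np.random.default_rng(3)
        ll = rng.normal(-3.0, 0.5, size=(300, 8))
        a, b = psis_loo(ll + 0.25), psis_loo(ll)
        c = compare_elpd(a, b)
        assert c.elpd_diff == pytest.approx(8 * 0.25, abs=1e-9)
        assert c.se_diff == pytest.approx(0.0, abs=1e-9)

    def test_se_matches_direct_variance_formula(self):
        rng = np.random.default_rng(4)
        pa = rng.normal(-2.0, 0.4, 25)
        pb = rng.normal(-2.2, 0.5, 25)
        a = LooResult(pa.sum(), 0.0, pa, np.zeros(25))
        b = LooResult(pb.sum(), 0.0, pb, np.zeros(25))
        c = compare_elpd(a, b)
        d = pa - pb
        assert c.se_diff == pytest.approx(
            np.sqrt(25 * (np.sum((d - d.mean()) ** 2) / 24)), rel=1e-12)

    def test_mismatched_n_rejected(self):
        a = LooResult(0.0, 0.0, np.zeros(5), np.zeros(5))
        b = LooResult(0.0, 0.0, np.zeros(6), np.zeros(6))
        with pytest.raises(InvalidParameterError):
            compare_elpd(a, b)


class TestReport:
    def test_coefficient_table_structure(self, recovery_study):
        res = recovery_study[0]
        rep = analysis.coefficient_table(res["linear"], res["data"])
        assert set(rep["regression_coefficients"]) == {
            f"beta{i}" for i in range(6)}
        assert "sigma_within" in rep["distributional_parameters"]
        assert len(rep["correlations"]) == 15
        assert rep["domain_slopes"]["severe"]["median"] > \
            rep["domain_slopes"]["moderate"]["median"]
        assert 0 <= rep["bayes_r2"]["median"] <= 1
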