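"""Mean function, likelihood/prior densities, sampler behaviour, R-hat."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from hrvent import models
from hrvent.models import (
    COL_DOMAIN,
    COL_HR,
    COL_SUBJECT,
    COL_VE,
    FixedEffects,
    InvalidParameterError,
    ModelForm,
    ModelParams,
    PriorSpec,
    StudentTPrior,
    SubjectDeviations,
    VarianceComponents,
    default_priors,
    lkj_logpdf,
    log_likelihood,
    log_prior,
    mu,
    rhat,
    sample_posterior,
    split_rhat,
)

from conftest import toy_dataset


class TestMu:
    def test_exponential_at_zero_hr_is_scale(self):
        fe = FixedEffects(ModelForm.EXPONENTIAL, [2.86, 0.019])
        assert mu(fe, 0.0) == pytest.approx(2.86)

    def test_linear_moderate_at_vt1_hr(self):
        fe = FixedEffects(ModelForm.LINEAR_DOMAINS,
                          [-32.92, 0.54, -69.02, 0.45, -235.89, 1.44])
        assert mu(fe, 153.0, domain="moderate") == pytest.approx(49.70)

    def test_exponential_printed_equation(self):
        fe = FixedEffects(ModelForm.EXPONENTIAL, [2.86, 0.019])
        assert mu(fe, 150.0) == pytest.approx(2.86 * np.exp(0.019 * 150.0))
        assert mu(fe, 150.0) == pytest.approx(49.44, abs=0.01)

    def test_subject_level_adds_deviation(self):
        fe = FixedEffects(ModelForm.EXPONENTIAL, [2.86, 0.019])
        params = ModelParams(
            fe, VarianceComponents(1.0, np.ones(2), np.eye(2)),
            SubjectDeviations([[1.0, 0.001], [0.0, 0.0]]),
        )
        assert mu(params, 100.0, subject=0) == pytest.approx(
            3.86 * np.exp(0.020 * 100.0))
        assert mu(params, 100.0, subject=1) == pytest.approx(
            2.86 * np.exp(0.019 * 100.0))

    def test_linear_requires_domain(self):
        fe = FixedEffects(ModelForm.LINEAR_DOMAINS, np.zeros(6))
        with pytest.raises(InvalidParameterError):
            mu(fe, 150.0)

    @given(hr=st.floats(40, 220), dhr=st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_exponential_strictly_increasing_in_hr(self, hr, dhr):
        fe = FixedEffects(ModelForm.EXPONENTIAL, [2.86, 0.019])
        assert mu(fe, hr + dhr) > mu(fe, hr)


def _exp_params(sigma=1.0, b=None):
    dev = SubjectDeviations(b) if b is not None else SubjectDeviations(
        np.zeros((1, 2)))
    return ModelParams(
        FixedEffects(ModelForm.EXPONENTIAL, [2.86, 0.019]),
        VarianceComponents(sigma, np.array([1.0, 0.01]), np.eye(2)),
        dev,
    )


class TestLogLikelihood:
    def test_single_observation_at_mode(self):
        params = _exp_params(sigma=1.0)
        ve = mu(params.fixed, 150.0)
        data = pd.DataFrame({COL_SUBJECT: ["a"], COL_HR: [150.0],
                             COL_VE: [ve]})
        assert log_likelihood(params, data) == pytest.approx(
            -0.5 * np.log(2 * np.pi), abs=1e-9)
        assert log_likelihood(params, data) == pytest.approx(-0.9189, abs=1e-4)

    def test_additivity_against_per_observation_oracle(self):
        params = _exp_params(sigma=2.0)
        hr = np.array([120.0, 180.0])
        ve = np.array([30.0, 95.0])
        data = pd.DataFrame({COL_SUBJECT: ["a", "a"], COL_HR: hr, COL_VE: ve})
        expected = sum(
            stats.norm.logpdf(v, mu(params.fixed, h), 2.0)
            for h, v in zip(hr, ve)
        )
        assert log_likelihood(params, data) == pytest.approx(expected, rel=1e-12)

    def test_doubling_sigma_at_zero_residuals(self):
        n = 7
        hr = np.linspace(120, 190, n)
        params1 = _exp_params(sigma=1.0)
        ve = np.array([mu(params1.fixed, h) for h in hr])
        data = pd.DataFrame({COL_SUBJECT: ["a"] * n, COL_HR: hr, COL_VE: ve})
        params2 = _exp_params(sigma=2.0)
        assert log_likelihood(params1, data) - log_likelihood(params2, data) \
            == pytest.approx(n * np.log(2.0))

    def test_exponential_overflow_gives_neg_inf(self):
        params = ModelParams(
            FixedEffects(ModelForm.EXPONENTIAL, [2.86, 5.0]),  # e^(5*150)
            VarianceComponents(1.0, np.array([1.0, 0.01]), np.eye(2)),
            SubjectDeviations(np.zeros((1, 2))),
        )
        data = pd.DataFrame({COL_SUBJECT: ["a"], COL_HR: [150.0],
                             COL_VE: [50.0]})
        assert np.isfinite(log_likelihood(params, data)) or \
            log_likelihood(params, data) == -np.inf
        # with exponent clipped at 50, mu is finite but astronomically large;
        # the density itself must never crash
        assert log_likelihood(params, data) < -1e10


class TestLogPrior:
    def test_lkj_eta1_2x2_uniform_in_rho(self):
        # implied marginal of the single correlation is uniform on (-1, 1):
        # the normalized density is 1/2 regardless of rho
        for rho in (-0.9, -0.3, 0.0, 0.7):
            R = np.array([[1.0, rho], [rho, 1.0]])
            assert lkj_logpdf(R, eta=1.0) == pytest.approx(np.log(0.5))

    def test_student_t_density_matches_textbook_formula(self):
        pr = StudentTPrior(3, 0.0, 2.5)
        for x in (0.0, 1.3, -4.0):
            nu, s = 3.0, 2.5
            expected = (
                special.gammaln(2.0) - special.gammaln(1.5)
                - 0.5 * np.log(nu * np.pi) - np.log(s)
                - 2.0 * np.log1p(x * x / (nu * s * s))
            )
            assert pr.logpdf(x) == pytest.approx(expected, rel=1e-12)

    def test_half_t_negative_sd_is_neg_inf(self):
        pr = StudentTPrior(3, 0.0, 2.5)
        assert pr.half_logpdf(-0.1) == -np.inf

    def test_joint_density_matches_bruteforce_oracle(self):
        """Term-by-term re-implementation on a 5-obs, 2-subject instance."""
        rng = np.random.default_rng(0)
        b = np.array([[0.5, 0.002], [-0.3, -0.001]])
        corr = np.array([[1.0, -0.5], [-0.5, 1.0]])
        params = ModelParams(
            FixedEffects(ModelForm.EXPONENTIAL, [3.0, 0.02]),
            VarianceComponents(2.0, np.array([1.5, 0.004]), corr),
            SubjectDeviations(b),
        )
        hr = rng.uniform(120, 190, 5)
        subj = ["a", "a", "a", "b", "b"]
        ve = rng.uniform(30, 90, 5)
        data = pd.DataFrame({COL_SUBJECT: subj, COL_HR: hr, COL_VE: ve})
        priors = default_priors("exponential")

        # --- independent oracle ---
        coef = params.fixed.beta[None, :] + b
        idx = np.array([0, 0, 0, 1, 1])
        mu_i = coef[idx, 0] * np.exp(coef[idx, 1] * hr)
        ll = stats.norm.logpdf(ve, mu_i, 2.0).sum()
        lp = stats.t.logpdf(3.0, 3, 4.2, 2.5) + stats.t.logpdf(0.02, 3, 0, 2.5)
        for sd in (2.0, 1.5, 0.004):
            lp += stats.t.logpdf(sd, 3, 0, 2.5) + np.log(2.0)
        lp += np.log(0.5)  # LKJ(1) on a 2x2 correlation
        S = np.diag([1.5, 0.004]) @ corr @ np.diag([1.5, 0.004])
        lp += stats.multivariate_normal.logpdf(b, np.zeros(2), S).sum()

        got = log_likelihood(params, data) + log_prior(params, priors)
        assert got == pytest.approx(ll + lp, rel=1e-10)


class TestSplitRhat:
    def test_same_distribution_chains_near_one(self):
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((4, 1000))
        assert split_rhat(chains) <= 1.01

    def test_offset_chains_much_greater_than_one(self):
        rng = np.random.default_rng(2)
        chains = rng.standard_normal((2, 500))
        chains[1] += 50.0
        assert split_rhat(chains) > 1.5

    def test_identical_constant_chains_exactly_one(self):
        assert split_rhat(np.ones((3, 100))) == 1.0

    def test_single_chain_rejected(self):
        with pytest.raises(InvalidParameterError):
            split_rhat(np.ones((1, 100)))

    def test_agrees_with_arviz_split_rhat(self):
        import arviz as az

        rng = np.random.default_rng(3)
        chains = rng.standard_normal((4, 500)) + 0.3 * rng.standard_normal((4, 1))
        mine = split_rhat(chains)
        ref = float(az.rhat(chains[None].transpose(1, 2, 0)[..., 0],
                            method="split"))
        assert mine == pytest.approx(ref, rel=1e-6)


class TestSampler:
    def test_gaussian_target_moments(self):
        from hrvent import _nuts

        cov = np.array([[2.0, 0.8], [0.8, 1.0]])
        prec = np.linalg.inv(cov)

        def lp(theta):
            return float(-0.5 * theta @ prec @ theta), -prec @ theta

        rng = np.random.default_rng(0)
        res = _nuts.sample_chain(lp, np.zeros(2), 300, 2000, rng, 0.8)
        assert np.allclose(res.draws.mean(0), 0.0, atol=0.15)
        assert np.allclose(np.cov(res.draws.T), cov, rtol=0.2, atol=0.15)

    def test_exponential_rate_recovered_in_cri(self):
        """Data from known exponential parameters: true rate inside 95% CrI."""
        from hrvent import analysis, synthetic

        grid = synthetic.DesignGrid(obs_full=25)
        data, truth, dev = synthetic.simulate_cohort_dataset(
            "exponential", seed=2, n_subjects=8, grid=grid)
        draws = sample_posterior(data, "exponential", chains=2,
                                 iterations=350, warmup=150, seed=2)
        s = analysis.summarize(draws, "beta1")
        assert s.lower <= 0.019 <= s.upper

    def test_fixed_effects_posterior_matches_ols(self):
        """Near-flat priors, fixed effects only: posterior within 2 SE of OLS."""
        rng = np.random.default_rng(4)
        n = 80
        hr = rng.uniform(114, 199, n)
        dom = np.where(hr < 153, "moderate",
                       np.where(hr < 172, "heavy", "severe"))
        X = models.design_matrix(hr, dom, ModelForm.LINEAR_DOMAINS)
        beta_true = np.array([-30.0, 0.5, -60.0, 0.4, -200.0, 1.3])
        sigma = 4.0
        ve = X @ beta_true + sigma * rng.standard_normal(n)
        data = pd.DataFrame({COL_SUBJECT: ["a"] * n, COL_HR: hr,
                             COL_DOMAIN: dom, COL_VE: ve})
        flat = PriorSpec(
            fixed=[StudentTPrior(3, 0.0, 1e4) for _ in range(6)],
            sd=StudentTPrior(3, 0.0, 1e4),
        )
        draws = sample_posterior(data, "linear_domains", priors=flat,
                                 chains=2, iterations=500, warmup=200,
                                 seed=4, hierarchical=False)
        coef, *_ = np.linalg.lstsq(X, ve, rcond=None)
        resid = ve - X @ coef
        s2 = resid @ resid / (n - 6)
        se = np.sqrt(s2 * np.diag(np.linalg.inv(X.T @ X)))
        post_mean = draws.beta.reshape(-1, 6).mean(axis=0)
        assert np.all(np.abs(post_mean - coef) < 2.0 * se)

    def test_prior_sampling_with_no_observations(self):
        """Empty dataset + proper priors: posterior quantiles ~ prior."""
        data = pd.DataFrame(columns=[COL_SUBJECT, COL_HR, COL_VE])
        draws = sample_posterior(data, "exponential", chains=2,
                                 iterations=1200, warmup=300, seed=1,
                                 hierarchical=False)
        prior = StudentTPrior(3, 4.2, 2.5)
        pooled = draws.pooled("beta0")
        for q in (0.25, 0.5, 0.75):
            assert np.quantile(pooled, q) == pytest.approx(
                prior.ppf(q), abs=0.35)

    def test_subject_relabelling_invariance(self):
        """Permuting subject labels changes no population-level summary
        beyond Monte-Carlo error."""
        from hrvent import analysis, synthetic

        grid = synthetic.DesignGrid(obs_full=20)
        data, truth, dev = synthetic.simulate_cohort_dataset(
            "exponential", seed=9, n_subjects=6, grid=grid)
        relabel = {s: f"Z{9 - i}" for i, s in
                   enumerate(sorted(data[COL_SUBJECT].unique()))}
        data2 = data.assign(**{COL_SUBJECT: data[COL_SUBJECT].map(relabel)})
        d1 = sample_posterior(data, "exponential", chains=2, iterations=400,
                              warmup=150, seed=3)
        d2 = sample_posterior(data2, "exponential", chains=2, iterations=400,
                              warmup=150, seed=3)
        s1 = analysis.summarize(d1, "beta1")
        s2 = analysis.summarize(d2, "beta1")
        sd = d1.pooled("beta1").std()
        assert abs(s1.median - s2.median) < 0.5 * sd

    def test_null_interaction_coefficients_covered(self, linear_truth):
        """Generator with beta2..beta5 = 0: their CrIs cover zero."""
        from hrvent import analysis, synthetic

        truth = ModelParams(
            FixedEffects(ModelForm.LINEAR_DOMAINS,
                         [-32.92, 0.54, 0.0, 0.0, 0.0, 0.0]),
            linear_truth.variance,
        )
        grid = synthetic.DesignGrid(obs_per_domain=8)
        data, _, dev = synthetic.simulate_cohort_dataset(
            "linear_domains", truth=truth, seed=12, n_subjects=10, grid=grid)
        draws = sample_posterior(data, "linear_domains", chains=2,
                                 iterations=400, warmup=150, seed=5)
        for name in ("beta2", "beta3", "beta4", "beta5"):
            s = analysis.summarize(draws, name)
            assert s.lower <= 0.0 <= s.upper

    def test_iterations_must_exceed_warmup(self, small_linear_dataset):
        data, _, _ = small_linear_dataset
        with pytest.raises(InvalidParameterError):
            sample_posterior(data, "linear_domains", iterations=100,
                             warmup=100)


class TestRhatOnFit:
    def test_rhat_reported_for_all_monitored_parameters(
            self, converged_linear_fit):
        diags = rhat(converged_linear_fit["draws"])
        assert "beta0" in diags and "sigma_within" in diags
        assert "rho_b0_b1" in diags and "b[0,0]" in diags
        assert all(np.isfinite(v) for v in diags.values())
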