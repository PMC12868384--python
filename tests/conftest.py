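"""Shared fixtures: small synthetic datasets and the multi-seed recovery study.

The recovery study (10 seeds, reduced design and chain lengths relative to
the full defaults) is session-scoped because it is by far the most
expensive piece of the suite and several tests consume it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hrvent import analysis, models, synthetic
from hrvent.models import COL_DOMAIN, COL_HR, COL_SUBJECT, COL_VE

N_STUDY_SEEDS = 10
# reduced study conditions for the test suite (the full defaults are
# 20 obs/domain and 4 chains x (500+500); see docs/methods.md)
STUDY_GRID = synthetic.DesignGrid(obs_per_domain=10, obs_full=30)
STUDY_CHAINS = 2
STUDY_ITER = 650      # linear-domains fits (coverage checks need the tails)
STUDY_WARMUP = 250
STUDY_ITER_EXP = 400  # exponential comparator: ELPD only
STUDY_WARMUP_EXP = 150


@pytest.fixture(scope="session")
def linear_truth() -> models.ModelParams:
    return synthetic.published_truth("linear_domains")


@pytest.fixture(scope="session")
def exponential_truth() -> models.ModelParams:
    return synthetic.published_truth("exponential")


def make_dataset(form="linear_domains", seed=0, n_subjects=19, grid=None):
    data, truth, dev = synthetic.simulate_cohort_dataset(
        form, seed=seed, n_subjects=n_subjects, grid=grid or STUDY_GRID
    )
    return data, truth, dev


@pytest.fixture(scope="session")
def small_linear_dataset():
    """6 subjects, 6 obs/domain — for quick functional tests."""
    grid = synthetic.DesignGrid(obs_per_domain=6, obs_full=18)
    return make_dataset("linear_domains", seed=5, n_subjects=6, grid=grid)


@pytest.fixture(scope="session")
def recovery_study(linear_truth):
    """Ten replicate cohorts from the linear-domains generative truth, each
    fit with both models, plus their ELPD-LOO comparison."""
    results = []
    for i in range(N_STUDY_SEEDS):
        data, truth, dev = make_dataset("linear_domains", seed=100 + i)
        lin = models.sample_posterior(
            data, "linear_domains", chains=STUDY_CHAINS, iterations=STUDY_ITER,
            warmup=STUDY_WARMUP, seed=i, target_accept=0.85,
        )
        exp = models.sample_posterior(
            data, "exponential", chains=STUDY_CHAINS,
            iterations=STUDY_ITER_EXP, warmup=STUDY_WARMUP_EXP, seed=i,
            target_accept=0.85,
        )
        comparison = analysis.compare_elpd(
            analysis.loo(lin, data), analysis.loo(exp, data)
        )
        results.append({
            "seed": i,
            "data": data,
            "truth": truth,
            "linear": lin,
            "exponential": exp,
            "elpd_diff": comparison,
        })
    return results


@pytest.fixture(scope="session")
def converged_linear_fit():
    """One longer 4-chain fit used for convergence-diagnostic checks."""
    grid = synthetic.DesignGrid(obs_per_domain=12, obs_full=36)
    data, truth, dev = make_dataset("linear_domains", seed=42, grid=grid)
    draws = models.sample_posterior(
        data, "linear_domains", chains=4, iterations=700, warmup=250, seed=7,
    )
    return {"data": data, "truth": truth, "draws": draws}


def degenerate_draws(beta, sigma_within, form="linear_domains",
                     chains=2, n=60) -> models.PosteriorDraws:
    """PosteriorDraws with every draw fixed at the given values (for exact
    derived-quantity arithmetic)."""
    form = models.ModelForm.coerce(form)
    k = form.n_coef
    beta_arr = np.tile(np.asarray(beta, dtype=float), (chains, n, 1))
    return models.PosteriorDraws(
        form=form,
        beta=beta_arr,
        sigma_within=np.full((chains, n), float(sigma_within)),
        sigma_b=None,
        corr=None,
        b=None,
        subject_ids=[],
    )


TABLE_LINEAR_BETA = [-32.92, 0.54, -69.02, 0.45, -235.89, 1.44]
TABLE_LINEAR_SIGMA = 3.50
TABLE_EXP_BETA = [2.86, 0.019]
TABLE_EXP_SIGMA = 5.01


def toy_dataset(rows) -> pd.DataFrame:
    """rows of (subject, hr, domain, ve) -> Dataset frame."""
    return pd.DataFrame(rows, columns=[COL_SUBJECT, COL_HR, COL_DOMAIN, COL_VE])
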