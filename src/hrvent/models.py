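"""Bayesian multilevel models linking minute ventilation (V̇E) to heart rate.

Two model forms are supported, both with a Gaussian observation model
``V̇E ~ Normal(mu_i, sigma_within)`` and subject-varying coefficients drawn
from a multivariate normal around the population coefficients:

* ``exponential`` — mu_i = beta0_j * exp(beta1_j * HR_i); two varying
  coefficients (scale and rate).
* ``linear_domains`` — mu_i = beta0_j + beta1_j*HR + beta2_j*I[heavy]
  + beta3_j*I[heavy]*HR + beta4_j*I[severe] + beta5_j*I[severe]*HR, with
  the moderate domain as the reference level; all six coefficients vary
  between subjects.

Between-subject structure: b_j ~ MVNormal(0, S) with
S = diag(sigma_b) · R · diag(sigma_b), R a full correlation matrix with an
LKJ(eta) prior.  Fixed effects carry Student-t priors, SD parameters
half-Student-t priors (locations/scales per :func:`default_priors`).

Posterior sampling is done by the package's own No-U-Turn sampler
(:mod:`hrvent._nuts`) on an unconstrained parameterization: log-SDs with
their Jacobians and the canonical partial-correlation transform for the
correlation matrix.  For the linear-domains form the subject effects are
marginalized analytically (Gaussian linear mixed model) and re-drawn
exactly per retained draw; the exponential form samples them directly
(centered), which is well conditioned under the informative per-subject
incremental-test designs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special

from hrvent import _nuts

logger = logging.getLogger(__name__)

# Canonical Dataset column names (shared with synthetic + io modules).
COL_SUBJECT = "subject_id"
COL_HR = "hr_bpm"
COL_DOMAIN = "domain"
COL_VE = "ve_l_min"

DOMAINS = ("moderate", "heavy", "severe")

#: exponent cap applied before exp() in the exponential mean function
EXP_CLIP = 50.0


class ModelForm(str, Enum):
    EXPONENTIAL = "exponential"
    LINEAR_DOMAINS = "linear_domains"

    @property
    def n_coef(self) -> int:
        return 2 if self is ModelForm.EXPONENTIAL else 6

    @classmethod
    def coerce(cls, form: "ModelForm | str") -> "ModelForm":
        if isinstance(form, cls):
            return form
        key = str(form).replace("-", "_").lower()
        return cls(key)


class InvalidParameterError(ValueError):
    """Raised for parameter values outside the model's support."""


@dataclass
class FixedEffects:
    """Population-level coefficients (beta0..beta{K-1}) for one model form."""

    form: ModelForm
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.form = ModelForm.coerce(self.form)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (self.form.n_coef,):
            raise InvalidParameterError(
                f"{self.form.value} form requires {self.form.n_coef} fixed "
                f"effects, got shape {self.beta.shape}"
            )


@dataclass
class VarianceComponents:
    """Residual SD, between-subject SDs and their correlation matrix."""

    sigma_within: float
    sigma_b: np.ndarray
    corr: np.ndarray

    def __post_init__(self) -> None:
        self.sigma_b = np.asarray(self.sigma_b, dtype=float)
        self.corr = np.asarray(self.corr, dtype=float)
        k = self.sigma_b.shape[0]
        if self.sigma_within <= 0:
            raise InvalidParameterError("sigma_within must be > 0")
        if np.any(self.sigma_b < 0):
            raise InvalidParameterError("sigma_b must be >= 0 elementwise")
        if self.corr.shape != (k, k):
            raise InvalidParameterError("corr shape must match sigma_b length")
        if not np.allclose(self.corr, self.corr.T, atol=1e-10):
            raise InvalidParameterError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.corr), 1.0, atol=1e-10):
            raise InvalidParameterError("correlation matrix needs unit diagonal")
        if np.linalg.eigvalsh(self.corr).min() < -1e-10:
            raise InvalidParameterError(
                "correlation matrix must be positive semi-definite"
            )

    @property
    def covariance(self) -> np.ndarray:
        """S = diag(sigma_b) · R · diag(sigma_b)."""
        d = np.diag(self.sigma_b)
        return d @ self.corr @ d


@dataclass
class SubjectDeviations:
    """Per-subject deviations b_j around the population coefficients."""

    b: np.ndarray  # (n_subjects, n_coef)

    def __post_init__(self) -> None:
        self.b = np.atleast_2d(np.asarray(self.b, dtype=float))

    @property
    def n_subjects(self) -> int:
        return self.b.shape[0]


@dataclass
class ModelParams:
    """Complete parameter state: simulator truth or one posterior draw."""

    fixed: FixedEffects
    variance: VarianceComponents
    deviations: SubjectDeviations | None = None

    @property
    def form(self) -> ModelForm:
        return self.fixed.form

    def subject_coefficients(self) -> np.ndarray:
        """(n_subjects, K) matrix of beta + b_j."""
        if self.deviations is None:
            raise InvalidParameterError("no subject deviations attached")
        return self.fixed.beta[None, :] + self.deviations.b


@dataclass
class StudentTPrior:
    nu: float
    loc: float
    scale: float

    def __post_init__(self) -> None:
        if self.nu <= 0 or self.scale <= 0:
            raise InvalidParameterError("Student-t prior needs nu > 0, scale > 0")

    def logpdf(self, x: np.ndarray | float) -> np.ndarray | float:
        z = (np.asarray(x, dtype=float) - self.loc) / self.scale
        return (
            special.gammaln((self.nu + 1) / 2)
            - special.gammaln(self.nu / 2)
            - 0.5 * np.log(self.nu * np.pi)
            - np.log(self.scale)
            - 0.5 * (self.nu + 1) * np.log1p(z * z / self.nu)
        )

    def half_logpdf(self, x: np.ndarray | float) -> np.ndarray | float:
        """Half-Student-t density on [0, inf) (loc must be 0)."""
        x = np.asarray(x, dtype=float)
        out = np.where(x < 0, -np.inf, self.logpdf(x) + np.log(2.0))
        return out if out.ndim else float(out)

    def ppf(self, q: np.ndarray | float) -> np.ndarray | float:
        from scipy import stats

        return stats.t.ppf(q, self.nu, loc=self.loc, scale=self.scale)


@dataclass
class PriorSpec:
    """Priors: Student-t per fixed effect, half-t for every SD, LKJ(eta) for R."""

    fixed: Sequence[StudentTPrior]
    sd: StudentTPrior
    lkj_eta: float = 1.0

    def __post_init__(self) -> None:
        if self.lkj_eta <= 0:
            raise InvalidParameterError("LKJ eta must be > 0")


def default_priors(form: ModelForm | str) -> PriorSpec:
    """The priors used in the source analyses (response-scale defaults)."""
    form = ModelForm.coerce(form)
    if form is ModelForm.EXPONENTIAL:
        return PriorSpec(
            fixed=[StudentTPrior(3, 4.2, 2.5), StudentTPrior(3, 0.0, 2.5)],
            sd=StudentTPrior(3, 0.0, 2.5),
        )
    return PriorSpec(
        fixed=[StudentTPrior(3, 64.7, 24.3)]
        + [StudentTPrior(3, 0.0, 24.3) for _ in range(5)],
        sd=StudentTPrior(3, 0.0, 24.3),
    )


# ---------------------------------------------------------------------------
# Dataset handling
# ---------------------------------------------------------------------------


def validate_dataset(data: pd.DataFrame, form: ModelForm | str) -> pd.DataFrame:
    form = ModelForm.coerce(form)
    required = [COL_SUBJECT, COL_HR, COL_VE]
    if form is ModelForm.LINEAR_DOMAINS:
        required.append(COL_DOMAIN)
    missing = [c for c in required if c not in data.columns]
    if missing:
        raise InvalidParameterError(f"dataset missing columns: {missing}")
    hr = np.asarray(data[COL_HR], dtype=float)
    if np.any((hr < 30) | (hr > 230)):
        raise InvalidParameterError("hr_bpm outside [30, 230]")
    if form is ModelForm.LINEAR_DOMAINS:
        bad = set(data[COL_DOMAIN].unique()) - set(DOMAINS)
        if bad:
            raise InvalidParameterError(f"unknown domain labels: {bad}")
    return data


def design_matrix(hr: np.ndarray, domain: np.ndarray | None, form: ModelForm) -> np.ndarray:
    """Design matrix with moderate as the reference domain (0/1 indicators)."""
    hr = np.atleast_1d(np.asarray(hr, dtype=float))
    if form is ModelForm.EXPONENTIAL:
        return np.column_stack([np.ones_like(hr), hr])
    if domain is None:
        raise InvalidParameterError("linear_domains form requires domain labels")
    domain = np.atleast_1d(np.asarray(domain, dtype=object))
    heavy = (domain == "heavy").astype(float)
    severe = (domain == "severe").astype(float)
    return np.column_stack(
        [np.ones_like(hr), hr, heavy, heavy * hr, severe, severe * hr]
    )


# ---------------------------------------------------------------------------
# Mean function, likelihood, prior
# ---------------------------------------------------------------------------


def mu(
    params: ModelParams | FixedEffects,
    hr: np.ndarray | float,
    domain: np.ndarray | str | None = None,
    subject: np.ndarray | int | None = None,
):
    """Expected V̇E (L·min⁻¹) at the given heart rate(s).

    ``subject=None`` evaluates the population-level mean (zero deviations);
    otherwise ``subject`` indexes rows of the attached deviations.
    """
    fixed = params.fixed if isinstance(params, ModelParams) else params
    form = fixed.form
    scalar = np.isscalar(hr)
    hr_arr = np.atleast_1d(np.asarray(hr, dtype=float))

    if subject is None:
        coef = np.broadcast_to(fixed.beta, (hr_arr.size, fixed.beta.size))
    else:
        if not isinstance(params, ModelParams) or params.deviations is None:
            raise InvalidParameterError("subject-level mu requires deviations")
        subj = np.broadcast_to(np.asarray(subject, dtype=int), hr_arr.shape)
        coef = fixed.beta[None, :] + params.deviations.b[subj]

    if form is ModelForm.EXPONENTIAL:
        expo = np.minimum(coef[:, 1] * hr_arr, EXP_CLIP)
        out = coef[:, 0] * np.exp(expo)
    else:
        if domain is None:
            raise InvalidParameterError("linear_domains form requires a domain")
        dom_arr = np.broadcast_to(np.atleast_1d(np.asarray(domain, dtype=object)), hr_arr.shape)
        x = design_matrix(hr_arr, dom_arr, form)
        out = np.sum(x * coef, axis=1)
    return float(out[0]) if scalar else out


def log_likelihood(params: ModelParams, data: pd.DataFrame, form: ModelForm | str | None = None) -> float:
    """Sum over observations of Normal(mu_i, sigma_within) log density."""
    form = ModelForm.coerce(form) if form is not None else params.form
    validate_dataset(data, form)
    sw = params.variance.sigma_within
    if sw <= 0:
        raise InvalidParameterError("sigma_within must be > 0")
    subj_codes = _subject_codes(data, params)
    dom = data[COL_DOMAIN].to_numpy() if COL_DOMAIN in data.columns else None
    m = mu(params, data[COL_HR].to_numpy(), dom, subject=subj_codes)
    if not np.all(np.isfinite(m)):
        logger.warning("non-finite mean function encountered; log-likelihood -inf")
        return -np.inf
    r = (data[COL_VE].to_numpy(dtype=float) - m) / sw
    n = r.size
    return float(-0.5 * np.sum(r * r) - n * np.log(sw) - 0.5 * n * np.log(2 * np.pi))


def _subject_codes(data: pd.DataFrame, params: ModelParams) -> np.ndarray | None:
    if params.deviations is None:
        return None
    codes, uniques = pd.factorize(data[COL_SUBJECT], sort=True)
    if len(uniques) > params.deviations.n_subjects:
        raise InvalidParameterError("more subjects in data than deviation rows")
    return codes


def lkj_logpdf(corr: np.ndarray, eta: float = 1.0) -> float:
    """Normalized LKJ log density of a correlation matrix.

    Density is c_K(eta) * det(R)^(eta-1); the constant follows from the
    C-vine representation with layer-wise Beta(b_k, b_k) partial
    correlations, b_k = eta + (K-1-k)/2.
    """
    corr = np.asarray(corr, dtype=float)
    k = corr.shape[0]
    sign, logdet = np.linalg.slogdet(corr)
    if sign <= 0:
        return -np.inf
    log_c = 0.0
    for layer in range(1, k):
        b = eta + (k - 1 - layer) / 2.0
        log_c -= (k - layer) * ((2 * b - 1) * np.log(2.0) + special.betaln(b, b))
    return float((eta - 1.0) * logdet + log_c)


def log_prior(params: ModelParams, priors: PriorSpec) -> float:
    """Joint log prior: Student-t fixed effects, half-t SDs, LKJ(eta) for R,
    and the MVNormal(0, S) term for subject deviations when present."""
    fixed, var = params.fixed, params.variance
    if len(priors.fixed) != fixed.beta.size:
        raise InvalidParameterError("prior count does not match fixed effects")
    total = float(sum(p.logpdf(b) for p, b in zip(priors.fixed, fixed.beta)))
    total += float(priors.sd.half_logpdf(var.sigma_within))
    for s in var.sigma_b:
        total += float(priors.sd.half_logpdf(s))
    if not np.isfinite(total):
        return -np.inf
    total += lkj_logpdf(var.corr, priors.lkj_eta)
    if params.deviations is not None:
        S = var.covariance
        b = params.deviations.b
        k = b.shape[1]
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            return -np.inf
        sol = np.linalg.solve(S, b.T)
        quad = np.sum(b.T * sol)
        total += -0.5 * quad - 0.5 * b.shape[0] * (logdet + k * np.log(2 * np.pi))
    return float(total)


# ---------------------------------------------------------------------------
# Posterior draws container
# ---------------------------------------------------------------------------

RHAT_FLAG = 1.05


@dataclass
class PosteriorDraws:
    """Post-warm-up draws, shaped (chain, draw, ...) per parameter."""

    form: ModelForm
    beta: np.ndarray            # (C, D, K)
    sigma_within: np.ndarray    # (C, D)
    sigma_b: np.ndarray | None  # (C, D, K)
    corr: np.ndarray | None     # (C, D, K, K)
    b: np.ndarray | None        # (C, D, J, K)
    subject_ids: list
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[1]

    @property
    def hierarchical(self) -> bool:
        return self.b is not None

    def pooled(self, name: str) -> np.ndarray:
        """Pooled 1-D draws of a named scalar parameter or derived quantity."""
        k = self.form.n_coef
        c, d = self.beta.shape[:2]
        if name.startswith("beta"):
            i = int(name[4:])
            if i >= k:
                raise KeyError(name)
            return self.beta[:, :, i].reshape(-1)
        if name == "sigma_within":
            return self.sigma_within.reshape(-1)
        if name.startswith("sigma_b"):
            if self.sigma_b is None:
                raise KeyError(name)
            i = int(name[7:])
            return self.sigma_b[:, :, i].reshape(-1)
        if name.startswith("rho_b"):
            if self.corr is None:
                raise KeyError(name)
            i, j = (int(s) for s in name[5:].split("_b"))
            return self.corr[:, :, i, j].reshape(-1)
        derived = {
            "slope_moderate": lambda: self.beta[:, :, 1],
            "slope_heavy": lambda: self.beta[:, :, 1] + self.beta[:, :, 3],
            "slope_severe": lambda: self.beta[:, :, 1] + self.beta[:, :, 5],
            "intercept_moderate": lambda: self.beta[:, :, 0],
            "intercept_heavy": lambda: self.beta[:, :, 0] + self.beta[:, :, 2],
            "intercept_severe": lambda: self.beta[:, :, 0] + self.beta[:, :, 4],
        }
        if name in derived:
            if self.form is not ModelForm.LINEAR_DOMAINS:
                raise InvalidParameterError(
                    f"{name} requires the linear_domains form"
                )
            return derived[name]().reshape(-1)
        raise KeyError(name)

    def scalar_parameters(self) -> dict[str, np.ndarray]:
        """All monitored scalar parameters as (chain, draw) arrays."""
        k = self.form.n_coef
        out = {f"beta{i}": self.beta[:, :, i] for i in range(k)}
        out["sigma_within"] = self.sigma_within
        if self.sigma_b is not None:
            for i in range(k):
                out[f"sigma_b{i}"] = self.sigma_b[:, :, i]
            for i in range(k):
                for j in range(i + 1, k):
                    out[f"rho_b{i}_b{j}"] = self.corr[:, :, i, j]
            for jdx in range(self.b.shape[2]):
                for i in range(k):
                    out[f"b[{jdx},{i}]"] = self.b[:, :, jdx, i]
        return out

    def draw_params(self, chain: int, draw: int) -> ModelParams:
        """Materialize one draw as a ModelParams state."""
        fixed = FixedEffects(self.form, self.beta[chain, draw])
        if self.hierarchical:
            var = VarianceComponents(
                self.sigma_within[chain, draw],
                self.sigma_b[chain, draw],
                self.corr[chain, draw],
            )
            dev = SubjectDeviations(self.b[chain, draw])
        else:
            kk = self.form.n_coef
            var = VarianceComponents(
                self.sigma_within[chain, draw], np.zeros(kk), np.eye(kk)
            )
            dev = None
        return ModelParams(fixed, var, dev)


# ---------------------------------------------------------------------------
# R-hat
# ---------------------------------------------------------------------------


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain Gelman–Rubin potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws). Chains are split in half;
    identical zero-variance chains return exactly 1.0 by convention.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise InvalidParameterError("split_rhat needs >= 2 chains")
    n = chains.shape[1]
    if n < 4:
        raise InvalidParameterError("split_rhat needs >= 4 draws per chain")
    half = n // 2
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n2 = split.shape
    means = split.mean(axis=1)
    w = split.var(axis=1, ddof=1).mean()
    b = n2 * means.var(ddof=1)
    if w == 0.0:
        return 1.0 if b == 0.0 else np.inf
    var_hat = (n2 - 1) / n2 * w + b / n2
    return float(np.sqrt(var_hat / w))


def rhat(draws: PosteriorDraws) -> dict[str, float]:
    """Split-R̂ for every monitored scalar parameter."""
    if draws.n_chains < 2:
        raise InvalidParameterError("rhat requires >= 2 chains")
    return {k: split_rhat(v) for k, v in draws.scalar_parameters().items()}


# ---------------------------------------------------------------------------
# Posterior sampling
# ---------------------------------------------------------------------------


def sample_posterior(
    data: pd.DataFrame,
    form: ModelForm | str,
    priors: PriorSpec | None = None,
    chains: int = 4,
    iterations: int = 4000,
    warmup: int = 1000,
    seed: int = 0,
    target_accept: float = 0.9,
    max_treedepth: int = 8,
    hierarchical: bool = True,
) -> PosteriorDraws:
    """Fit a model by NUTS and return post-warm-up draws with diagnostics.

    ``iterations`` counts per-chain iterations *including* warm-up, so the
    default 4000/1000 yields 3000 retained draws per chain.
    """
    form = ModelForm.coerce(form)
    priors = priors or default_priors(form)
    if iterations <= warmup:
        raise InvalidParameterError("iterations must exceed warmup")
    if chains < 2:
        raise InvalidParameterError("need >= 2 chains for diagnostics")
    data = data.reset_index(drop=True)
    if len(data):
        validate_dataset(data, form)
        codes, uniques = pd.factorize(data[COL_SUBJECT], sort=True)
        subject_ids = list(uniques)
    else:
        codes, subject_ids = np.zeros(0, dtype=int), []
    if hierarchical and len(subject_ids) < 2 and len(data):
        raise InvalidParameterError("hierarchical fit needs >= 2 subjects")

    hr_arr = data[COL_HR].to_numpy(dtype=float) if len(data) else np.zeros(0)
    ve_arr = data[COL_VE].to_numpy(dtype=float) if len(data) else np.zeros(0)
    dom_arr = (
        data[COL_DOMAIN].to_numpy()
        if COL_DOMAIN in data.columns and len(data)
        else None
    )
    if form is ModelForm.LINEAR_DOMAINS and hierarchical and len(subject_ids):
        # Gaussian linear mixed model: subject effects are marginalized
        # analytically and re-drawn exactly per retained draw
        target = _nuts.MarginalLinearTarget(
            hr=hr_arr, ve=ve_arr, domain=dom_arr,
            subject=np.asarray(codes, dtype=int),
            n_subjects=len(subject_ids), priors=priors,
        )
    else:
        target = _nuts.HierarchicalTarget(
            form=form, hr=hr_arr, ve=ve_arr, domain=dom_arr,
            subject=np.asarray(codes, dtype=int),
            n_subjects=len(subject_ids), priors=priors,
            hierarchical=hierarchical,
        )

    n_draws = iterations - warmup
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(chains)

    def run_chain(chain_seed):
        rng = np.random.default_rng(chain_seed)
        theta0 = target.initial_state(rng)
        return _nuts.sample_chain(
            target.logp_grad,
            theta0,
            n_warmup=warmup,
            n_draws=n_draws,
            rng=rng,
            target_accept=target_accept,
            max_treedepth=max_treedepth,
            metric_cov0=target.metric_seed(theta0),
        )

    results = [run_chain(chain_seeds[c]) for c in range(chains)]
    # retry chains whose step-size adaptation collapsed (an occasional
    # warm-up failure mode): their step size sits orders of magnitude
    # below the other chains' and the chain barely moves
    eps_med = float(np.median([r.step_size for r in results]))
    for c, res in enumerate(results):
        if res.step_size < 1e-2 * eps_med:
            logger.warning(
                "chain %d step size %.2e << median %.2e; re-running once",
                c, res.step_size, eps_med,
            )
            results[c] = run_chain(chain_seeds[c].spawn(1)[0])

    chain_out = [r.draws for r in results]
    divergences = [r.divergences for r in results]
    accept_means = [r.mean_accept for r in results]

    raw = np.stack(chain_out)  # (C, D, dim)
    draws = target.unpack_draws(
        raw, subject_ids, rng=np.random.default_rng(ss.spawn(1)[0])
    )
    draws.meta.update(
        chains=chains,
        iterations=iterations,
        warmup=warmup,
        seed=seed,
        divergences=[int(d) for d in divergences],
        mean_accept=[float(a) for a in accept_means],
    )
    diags = rhat(draws)
    max_rhat = max(diags.values()) if diags else 1.0
    draws.meta["rhat"] = {k: float(v) for k, v in diags.items()}
    draws.meta["max_rhat"] = float(max_rhat)
    draws.meta["converged"] = bool(max_rhat <= RHAT_FLAG)
    if not draws.meta["converged"]:
        warnings.warn(
            f"convergence flagged: max split-R^ = {max_rhat:.3f} > {RHAT_FLAG}",
            RuntimeWarning,
            stacklevel=2,
        )
    if len(data) and COL_DOMAIN in data.columns:
        support = {
            str(d): [float(g[COL_HR].min()), float(g[COL_HR].max())]
            for d, g in data.groupby(COL_DOMAIN, observed=True)
        }
    elif len(data):
        support = {"all": [float(data[COL_HR].min()), float(data[COL_HR].max())]}
    else:
        support = {}
    draws.meta["hr_support"] = support
    return draws
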