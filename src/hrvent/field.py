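"""Estimate V̇E time series from field heart-rate logs.

For exposure assessment, a chest-strap HR log is converted to a V̇E
series with 95% individual prediction bounds, using either the published
regression equations or a fitted posterior.  Domains are assigned from HR
alone: user-supplied VT threshold HRs when available, otherwise the
default fractions of HRpeak (VT1 ≈ 80%, VT2 ≈ 90% HRpeak, with
HRpeak = 220 − age when unmeasured).  A heart rate equal to a threshold
belongs to the higher domain, matching the segmentation convention.

The published linear-domain equations are discontinuous at the domain
boundaries; the discontinuities are preserved (and reported), not
smoothed.  An optional hysteresis suppresses domain-label chattering when
HR oscillates around a boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hrvent.models import InvalidParameterError, ModelForm, PosteriorDraws

logger = logging.getLogger(__name__)

VT1_HRPEAK_FRACTION = 0.80
VT2_HRPEAK_FRACTION = 0.90

HRLOG_COLUMNS = ["timestamp_s", "hr_bpm"]
PREDICTION_COLUMNS = [
    "timestamp_s", "hr_bpm", "domain", "ve_median", "ve_lower", "ve_upper",
    "extrapolated",
]


@dataclass
class HrLog:
    samples: pd.DataFrame  # timestamp_s, hr_bpm
    subject_id: str | None = None
    hr_peak: float | None = None
    age_yr: float | None = None
    vt1_hr: float | None = None
    vt2_hr: float | None = None

    def __post_init__(self) -> None:
        missing = [c for c in HRLOG_COLUMNS if c not in self.samples.columns]
        if missing:
            raise InvalidParameterError(f"HR log missing columns: {missing}")
        t = self.samples["timestamp_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise InvalidParameterError("timestamps must be increasing")
        hr = self.samples["hr_bpm"].to_numpy(dtype=float)
        if np.any((hr < 30) | (hr > 230)):
            raise InvalidParameterError("hr_bpm outside [30, 230]")


@dataclass
class LinearEquation:
    intercept: float
    slope: float

    def __call__(self, hr):
        return self.intercept + self.slope * np.asarray(hr, dtype=float)


@dataclass
class EquationRegistry:
    """Coefficients of the published V̇E-from-HR equations.

    The exponential pair comes from the single-equation model; the three
    domain equations use the composite intercepts/slopes (the domain-slope
    values as printed in the results table, not the abstract's typo for
    the moderate slope — see the package docs).
    """

    exponential_scale: float = 2.86
    exponential_rate: float = 0.019
    exponential_sigma: float = 5.01
    linear: dict = field(default_factory=lambda: {
        "moderate": LinearEquation(-32.92, 0.54),
        "heavy": LinearEquation(-101.94, 0.99),
        "severe": LinearEquation(-268.81, 1.98),
    })
    linear_sigma: float = 3.50
    #: published per-domain HR support (extrapolation bounds)
    hr_support: dict = field(default_factory=lambda: {
        "moderate": (114.0, 171.0),
        "heavy": (141.0, 188.0),
        "severe": (157.0, 199.0),
        "all": (114.0, 199.0),
    })


def load_published_equations() -> EquationRegistry:
    return EquationRegistry()


def resolve_thresholds(
    vt1_hr: float | None = None,
    vt2_hr: float | None = None,
    hr_peak: float | None = None,
    age_yr: float | None = None,
) -> tuple[float, float]:
    """VT threshold HRs, falling back to %HRpeak and the 220 − age rule."""
    if vt1_hr is not None and vt2_hr is not None:
        if not vt1_hr < vt2_hr:
            raise InvalidParameterError("vt1_hr must be below vt2_hr")
        return float(vt1_hr), float(vt2_hr)
    if hr_peak is None:
        if age_yr is None:
            raise InvalidParameterError(
                "need vt1_hr/vt2_hr, or hr_peak, or age to assign domains"
            )
        hr_peak = 220.0 - age_yr
    return (
        float(vt1_hr) if vt1_hr is not None else VT1_HRPEAK_FRACTION * hr_peak,
        float(vt2_hr) if vt2_hr is not None else VT2_HRPEAK_FRACTION * hr_peak,
    )


def assign_domain_from_hr(
    hr,
    vt1_hr: float | None = None,
    vt2_hr: float | None = None,
    hr_peak: float | None = None,
    age_yr: float | None = None,
):
    """moderate below VT1, heavy in [VT1, VT2), severe at or above VT2."""
    vt1, vt2 = resolve_thresholds(vt1_hr, vt2_hr, hr_peak, age_yr)
    hr_arr = np.asarray(hr, dtype=float)
    out = np.where(hr_arr < vt1, "moderate", np.where(hr_arr < vt2, "heavy", "severe"))
    return str(out[()]) if np.isscalar(hr) else out


def _apply_hysteresis(domains: np.ndarray, t: np.ndarray, window_s: float) -> np.ndarray:
    """Suppress domain-label switches that revert within ``window_s``."""
    out = domains.copy()
    last_switch_t, cur = t[0], out[0]
    for i in range(1, len(out)):
        if out[i] != cur:
            if t[i] - last_switch_t < window_s:
                out[i] = cur
            else:
                last_switch_t, cur = t[i], out[i]
    return out


def _fit_equations(draws: PosteriorDraws, subject: str | None):
    """Posterior-median equations (population or subject level) from a fit."""
    from hrvent import analysis

    med = lambda q: analysis.summarize(draws, q).median
    offset = np.zeros(draws.form.n_coef)
    if subject is not None:
        if draws.b is None or subject not in draws.subject_ids:
            raise InvalidParameterError(f"subject {subject!r} was not in the fit")
        jdx = draws.subject_ids.index(subject)
        offset = np.median(draws.b[:, :, jdx, :].reshape(-1, draws.form.n_coef), axis=0)
    sw = med("sigma_within")
    support = draws.meta.get("hr_support", {})
    if draws.form is ModelForm.EXPONENTIAL:
        return {
            "form": ModelForm.EXPONENTIAL,
            "scale": med("beta0") + offset[0],
            "rate": med("beta1") + offset[1],
            "sigma": sw,
            "support": support,
        }
    eqs = {}
    for d, (i_int, i_sl) in {"moderate": (None, None), "heavy": (2, 3), "severe": (4, 5)}.items():
        intercept = med("beta0") + offset[0]
        slope = med("beta1") + offset[1]
        if i_int is not None:
            intercept += med(f"beta{i_int}") + offset[i_int]
            slope += med(f"beta{i_sl}") + offset[i_sl]
        eqs[d] = LinearEquation(intercept, slope)
    return {"form": ModelForm.LINEAR_DOMAINS, "linear": eqs, "sigma": sw, "support": support}


def domain_discontinuities(
    registry: EquationRegistry, vt1_hr: float, vt2_hr: float
) -> dict[str, float]:
    """Jump magnitude of predicted V̇E at each domain boundary (L·min⁻¹)."""
    return {
        "vt1": float(registry.linear["heavy"](vt1_hr) - registry.linear["moderate"](vt1_hr)),
        "vt2": float(registry.linear["severe"](vt2_hr) - registry.linear["heavy"](vt2_hr)),
    }


def predict_ve(
    log: HrLog,
    fit: EquationRegistry | PosteriorDraws | None = None,
    level: str = "population",
    model: ModelForm | str = ModelForm.LINEAR_DOMAINS,
    vt1_hr: float | None = None,
    vt2_hr: float | None = None,
    hysteresis_s: float = 0.0,
) -> pd.DataFrame:
    """Per-timestamp V̇E estimate with 95% individual prediction bounds.

    Bounds are mu ± 1.96·sigma_within (posterior medians when draws are
    supplied).  The ``extrapolated`` flag marks HR values outside the
    equations' per-domain HR support.
    """
    fit = fit if fit is not None else load_published_equations()
    model = ModelForm.coerce(model)
    t = log.samples["timestamp_s"].to_numpy(dtype=float)
    hr = log.samples["hr_bpm"].to_numpy(dtype=float)

    vt1, vt2 = resolve_thresholds(
        vt1_hr if vt1_hr is not None else log.vt1_hr,
        vt2_hr if vt2_hr is not None else log.vt2_hr,
        log.hr_peak,
        log.age_yr,
    )
    domains = assign_domain_from_hr(hr, vt1, vt2)
    if hysteresis_s > 0:
        domains = _apply_hysteresis(domains, t, hysteresis_s)

    if isinstance(fit, PosteriorDraws):
        eq = _fit_equations(fit, log.subject_id if level == "subject" else None)
        model = eq["form"]
        sigma = eq["sigma"]
        support = eq["support"]
        if model is ModelForm.EXPONENTIAL:
            mu_v = eq["scale"] * np.exp(eq["rate"] * hr)
        else:
            mu_v = np.empty_like(hr)
            for d in ("moderate", "heavy", "severe"):
                mask = domains == d
                mu_v[mask] = eq["linear"][d](hr[mask])
    else:
        if level == "subject":
            raise InvalidParameterError("published equations are population-level")
        support = fit.hr_support
        if model is ModelForm.EXPONENTIAL:
            sigma = fit.exponential_sigma
            mu_v = fit.exponential_scale * np.exp(fit.exponential_rate * hr)
        else:
            sigma = fit.linear_sigma
            mu_v = np.empty_like(hr)
            for d in ("moderate", "heavy", "severe"):
                mask = domains == d
                mu_v[mask] = fit.linear[d](hr[mask])

    extrapolated = np.zeros(hr.size, dtype=bool)
    for i, (h, d) in enumerate(zip(hr, domains)):
        key = d if (model is ModelForm.LINEAR_DOMAINS and d in support) else "all"
        lo, hi = support.get(key, (np.inf, -np.inf))
        extrapolated[i] = not (lo <= h <= hi)
    n_ex = int(extrapolated.sum())
    if n_ex:
        logger.warning("%d/%d HR samples outside the fitted HR support", n_ex, hr.size)
    if model is ModelForm.LINEAR_DOMAINS and isinstance(fit, EquationRegistry):
        logger.info("domain discontinuities: %s", domain_discontinuities(fit, vt1, vt2))

    half = 1.96 * sigma
    return pd.DataFrame({
        "timestamp_s": t,
        "hr_bpm": hr,
        "domain": domains,
        "ve_median": mu_v,
        "ve_lower": mu_v - half,
        "ve_upper": mu_v + half,
        "extrapolated": extrapolated,
    })
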