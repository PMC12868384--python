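"""Synthetic cohorts with the statistical structure the models assume.

The study's raw data are not deposited, so this module generates:

* subject-level regression coefficients drawn around the population
  coefficients with covariance S = diag(sigma_b)·R·diag(sigma_b)
  (:func:`draw_subject_effects`),
* V̇E-vs-HR observation tables per exercise-intensity domain
  (:func:`simulate_domain_observations`),
* whole incremental-treadmill-test traces at 1 Hz, with planted
  ventilatory-equivalent breakpoints, for exercising the segmentation
  stage (:func:`simulate_incremental_test`),
* cohorts of subject physiologies whose VT1/VT2/peak HR statistics
  converge to the published cohort anchors (:func:`emulate_cohort`).

The default anchors and model truths are the published posterior medians
(19 physically active females; incremental protocol 5-min warm-up at
6 km·h⁻¹ then +1 km·h⁻¹·min⁻¹ at 1% incline).  All randomness flows from
one integer seed through numpy Generators; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from hrvent.models import (
    COL_DOMAIN,
    COL_HR,
    COL_SUBJECT,
    COL_VE,
    DOMAINS,
    FixedEffects,
    InvalidParameterError,
    ModelForm,
    ModelParams,
    SubjectDeviations,
    VarianceComponents,
    mu,
)
from hrvent.segmentation import BreathTrace

# ---------------------------------------------------------------------------
# Protocol / physiology / anchors
# ---------------------------------------------------------------------------


@dataclass
class ProtocolSpec:
    """Incremental treadmill protocol."""

    warmup_speed_kmh: float = 6.0
    warmup_duration_s: float = 300.0
    increment_kmh: float = 1.0
    stage_duration_s: float = 60.0
    incline_pct: float = 1.0  # metadata only

    def __post_init__(self) -> None:
        if self.warmup_duration_s <= 0 or self.stage_duration_s <= 0:
            raise InvalidParameterError("durations must be > 0")
        if self.increment_kmh <= 0:
            raise InvalidParameterError("increment must be > 0")


@dataclass
class SubjectPhysiology:
    subject_id: str
    age_yr: float
    hr_peak: float
    vt1_hr: float
    vt2_hr: float
    hr_at_warmup_end: float
    vo2_peak_ml_min: float
    body_mass_kg: float = 63.1
    peak_speed_kmh: float = 14.0

    def __post_init__(self) -> None:
        if not (self.hr_at_warmup_end < self.vt1_hr < self.vt2_hr < self.hr_peak):
            raise InvalidParameterError(
                "require hr_at_warmup_end < vt1_hr < vt2_hr < hr_peak"
            )
        if self.hr_peak > 230:
            raise InvalidParameterError("hr_peak must be <= 230")


@dataclass
class Anchor:
    mean: float
    sd: float
    min: float | None = None
    max: float | None = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise InvalidParameterError("anchor SD must be >= 0")
        if self.min is not None and self.max is not None:
            if not (self.min <= self.mean <= self.max):
                raise InvalidParameterError("anchor mean outside printed range")


@dataclass
class CohortAnchors:
    """Cohort-level mean/SD (and printed ranges) of the key quantities."""

    n_subjects: int = 19
    vt1_hr: Anchor = field(default_factory=lambda: Anchor(153.0, 9.0, 138, 166))
    vt2_hr: Anchor = field(default_factory=lambda: Anchor(172.0, 9.0, 157, 188))
    hr_peak: Anchor = field(default_factory=lambda: Anchor(190.0, 6.0, 175, 202))
    peak_speed_kmh: Anchor = field(default_factory=lambda: Anchor(14.0, 1.5, 11.5, 16.7))
    vo2_peak_ml_min: Anchor = field(
        default_factory=lambda: Anchor(2807.2, 419.0, 2192.4, 3478.9)
    )
    age_yr: Anchor = field(default_factory=lambda: Anchor(29.3, 7.2, 18, 45))
    body_mass_kg: Anchor = field(default_factory=lambda: Anchor(63.1, 5.0))
    #: warm-up-end HR as a fraction of HRpeak (lowest observed HR ≈ 57% HRpeak)
    warmup_hr_fraction: float = 0.57

    def __post_init__(self) -> None:
        if not (self.vt1_hr.mean < self.vt2_hr.mean < self.hr_peak.mean):
            raise InvalidParameterError(
                "anchors must satisfy VT1 mean < VT2 mean < HRpeak mean"
            )


TABLE_ANCHORS = CohortAnchors()


@dataclass
class DesignGrid:
    """Per-domain HR sampling design for the regression datasets.

    The per-domain bounds are the published population HR supports; per
    subject they are intersected with that subject's threshold-delimited
    domain intervals so domain boundaries align with vt1/vt2.
    """

    hr_ranges: dict = field(
        default_factory=lambda: {
            "moderate": (114.0, 171.0),
            "heavy": (141.0, 188.0),
            "severe": (157.0, 199.0),
        }
    )
    obs_per_domain: int = 20
    full_range: tuple = (114.0, 199.0)  # single-equation (exponential) design
    obs_full: int = 60

    def __post_init__(self) -> None:
        for dom, (lo, hi) in self.hr_ranges.items():
            if not (30 <= lo < hi <= 230):
                raise InvalidParameterError(f"invalid HR range for {dom}")
        if self.obs_per_domain < 1 or self.obs_full < 1:
            raise InvalidParameterError("observation counts must be >= 1")


# ---------------------------------------------------------------------------
# Published-truth parameter sets (posterior medians used as simulator truth)
# ---------------------------------------------------------------------------


def _linear_truth() -> ModelParams:
    rho = {
        (0, 1): -0.79, (0, 2): 0.15, (0, 3): 0.03, (0, 4): 0.21, (0, 5): -0.19,
        (1, 2): -0.02, (1, 3): 0.09, (1, 4): -0.06, (1, 5): 0.31,
        (2, 3): -0.13, (2, 4): 0.18, (2, 5): 0.04,
        (3, 4): 0.17, (3, 5): 0.15, (4, 5): -0.42,
    }
    corr = np.eye(6)
    for (i, j), v in rho.items():
        corr[i, j] = corr[j, i] = v
    return ModelParams(
        fixed=FixedEffects(
            ModelForm.LINEAR_DOMAINS,
            np.array([-32.92, 0.54, -69.02, 0.45, -235.89, 1.44]),
        ),
        variance=VarianceComponents(
            sigma_within=3.50,
            sigma_b=np.array([25.73, 0.19, 2.88, 0.02, 15.39, 0.11]),
            corr=corr,
        ),
    )


def _exponential_truth() -> ModelParams:
    return ModelParams(
        fixed=FixedEffects(ModelForm.EXPONENTIAL, np.array([2.86, 0.019])),
        variance=VarianceComponents(
            sigma_within=5.01,
            sigma_b=np.array([7.28, 0.005]),
            corr=np.array([[1.0, -0.94], [-0.94, 1.0]]),
        ),
    )


def published_truth(form: ModelForm | str) -> ModelParams:
    """Published posterior medians packaged as generative ground truth."""
    form = ModelForm.coerce(form)
    return _linear_truth() if form is ModelForm.LINEAR_DOMAINS else _exponential_truth()


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def draw_subject_effects(
    truth: ModelParams, n_subjects: int, seed: int | np.random.SeedSequence = 0
) -> SubjectDeviations:
    """Draw b_j ~ MVNormal(0, S) with S = diag(sigma_b)·R·diag(sigma_b)."""
    if n_subjects < 1:
        raise InvalidParameterError("n_subjects must be >= 1")
    var = truth.variance
    eig = np.linalg.eigvalsh(var.corr)
    if eig.min() < -1e-10:
        raise InvalidParameterError("correlation matrix not positive semi-definite")
    rng = np.random.default_rng(seed)
    k = var.sigma_b.size
    # eigendecomposition handles PSD (singular) matrices that Cholesky cannot
    w, v = np.linalg.eigh(var.corr)
    root = v @ np.diag(np.sqrt(np.maximum(w, 0.0))) @ v.T
    z = rng.standard_normal((n_subjects, k))
    b = (z @ root.T) * var.sigma_b[None, :]
    return SubjectDeviations(b=b)


def emulate_cohort(
    anchors: CohortAnchors = TABLE_ANCHORS,
    seed: int | np.random.SeedSequence = 0,
    n_subjects: int | None = None,
) -> list[SubjectPhysiology]:
    """Draw subject physiologies whose cohort statistics match the anchors.

    Marginal draws are Gaussian at the anchor mean/SD; tuples violating the
    ordering invariant (warm-up HR < VT1 < VT2 < HRpeak <= 230) are
    resampled, which perturbs the realized means by well under 1 bpm.
    """
    n = n_subjects if n_subjects is not None else anchors.n_subjects
    if n < 2:
        raise InvalidParameterError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        for _ in range(1000):
            hp = rng.normal(anchors.hr_peak.mean, anchors.hr_peak.sd)
            vt1 = rng.normal(anchors.vt1_hr.mean, anchors.vt1_hr.sd)
            vt2 = rng.normal(anchors.vt2_hr.mean, anchors.vt2_hr.sd)
            hw = anchors.warmup_hr_fraction * hp * (1 + 0.02 * rng.standard_normal())
            if hw < vt1 < vt2 < hp <= 230:
                break
        else:  # pragma: no cover - anchors would have to be degenerate
            raise InvalidParameterError("could not satisfy ordering invariants")
        out.append(
            SubjectPhysiology(
                subject_id=f"S{i:03d}",
                age_yr=float(np.clip(rng.normal(anchors.age_yr.mean, anchors.age_yr.sd), 18, 45)),
                hr_peak=float(hp),
                vt1_hr=float(vt1),
                vt2_hr=float(vt2),
                hr_at_warmup_end=float(hw),
                vo2_peak_ml_min=float(
                    np.clip(
                        rng.normal(anchors.vo2_peak_ml_min.mean, anchors.vo2_peak_ml_min.sd),
                        1500,
                        4500,
                    )
                ),
                body_mass_kg=float(
                    np.clip(rng.normal(anchors.body_mass_kg.mean, anchors.body_mass_kg.sd), 45, 90)
                ),
                peak_speed_kmh=float(
                    np.clip(
                        rng.normal(anchors.peak_speed_kmh.mean, anchors.peak_speed_kmh.sd),
                        9, 18,
                    )
                ),
            )
        )
    return out


def _subject_domain_interval(
    phys: SubjectPhysiology | None, domain: str, grid: DesignGrid
) -> tuple[float, float]:
    lo_grid, hi_grid = grid.hr_ranges[domain]
    if phys is None:
        phys_vt1, phys_vt2, phys_peak = (
            TABLE_ANCHORS.vt1_hr.mean,
            TABLE_ANCHORS.vt2_hr.mean,
            TABLE_ANCHORS.hr_peak.mean,
        )
    else:
        phys_vt1, phys_vt2, phys_peak = phys.vt1_hr, phys.vt2_hr, phys.hr_peak
    if domain == "moderate":
        lo, hi = lo_grid, min(phys_vt1, hi_grid)
    elif domain == "heavy":
        lo, hi = max(phys_vt1, lo_grid), min(phys_vt2, hi_grid)
    else:
        lo, hi = max(phys_vt2, lo_grid), min(phys_peak, hi_grid)
    if hi <= lo:
        raise InvalidParameterError(
            f"empty {domain} HR interval for subject "
            f"{(phys.subject_id if phys else '<population>')}"
        )
    return lo, hi


def _grid_points(lo: float, hi: float, n: int) -> np.ndarray:
    """Evenly spaced midpoints: a deterministic uniform design on [lo, hi)."""
    return lo + (np.arange(n) + 0.5) * (hi - lo) / n


def simulate_domain_observations(
    truth: ModelParams,
    deviations: SubjectDeviations,
    grid: DesignGrid,
    form: ModelForm | str,
    seed: int | np.random.SeedSequence = 0,
    physiologies: list[SubjectPhysiology] | None = None,
) -> pd.DataFrame:
    """One row per (subject, domain, HR): V̇E = mu_i + Normal(0, sigma_within).

    For the linear_domains form each subject gets ``grid.obs_per_domain``
    evenly spaced HR points per domain between that subject's thresholds;
    for the exponential form, ``grid.obs_full`` points across the full
    incremental range.  Domain labels are always attached (from the
    subject's thresholds) so the same table can be fit with either model.
    """
    form = ModelForm.coerce(form)
    if (form is ModelForm.LINEAR_DOMAINS and grid.obs_per_domain < 1) or (
        form is ModelForm.EXPONENTIAL and grid.obs_full < 1
    ):
        raise InvalidParameterError("empty design grid")
    n_subjects = deviations.n_subjects
    if physiologies is not None and len(physiologies) != n_subjects:
        raise InvalidParameterError("physiologies length must match deviations")
    rng = np.random.default_rng(seed)
    params = ModelParams(truth.fixed, truth.variance, deviations)
    rows = []
    for j in range(n_subjects):
        phys = physiologies[j] if physiologies is not None else None
        sid = phys.subject_id if phys is not None else f"S{j:03d}"
        vt1 = phys.vt1_hr if phys else TABLE_ANCHORS.vt1_hr.mean
        vt2 = phys.vt2_hr if phys else TABLE_ANCHORS.vt2_hr.mean
        if form is ModelForm.LINEAR_DOMAINS:
            if not vt1 < vt2:
                raise InvalidParameterError("subject thresholds out of order")
            for domain in DOMAINS:
                lo, hi = _subject_domain_interval(phys, domain, grid)
                hr = _grid_points(lo, hi, grid.obs_per_domain)
                m = mu(params, hr, domain=domain, subject=np.full(hr.size, j))
                ve = m + truth.variance.sigma_within * rng.standard_normal(hr.size)
                rows.append(pd.DataFrame({
                    COL_SUBJECT: sid, COL_HR: hr, COL_DOMAIN: domain, COL_VE: ve,
                }))
        else:
            lo, hi = grid.full_range
            hi = min(hi, phys.hr_peak if phys else TABLE_ANCHORS.hr_peak.mean)
            hr = _grid_points(lo, hi, grid.obs_full)
            m = mu(params, hr, subject=np.full(hr.size, j))
            ve = m + truth.variance.sigma_within * rng.standard_normal(hr.size)
            domain = np.where(hr < vt1, "moderate", np.where(hr < vt2, "heavy", "severe"))
            rows.append(pd.DataFrame({
                COL_SUBJECT: sid, COL_HR: hr, COL_DOMAIN: domain, COL_VE: ve,
            }))
    return pd.concat(rows, ignore_index=True)


def simulate_cohort_dataset(
    form: ModelForm | str = ModelForm.LINEAR_DOMAINS,
    truth: ModelParams | None = None,
    n_subjects: int = 19,
    grid: DesignGrid | None = None,
    seed: int | np.random.SeedSequence = 0,
    use_cohort_physiology: bool = True,
) -> tuple[pd.DataFrame, ModelParams, SubjectDeviations]:
    """End-to-end convenience: cohort → deviations → observation table.

    Returns the dataset together with the generative truth and the drawn
    deviations (for parameter-recovery checks).
    """
    form = ModelForm.coerce(form)
    truth = truth if truth is not None else published_truth(form)
    grid = grid or DesignGrid()
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_phys, s_dev, s_obs = ss.spawn(3)
    phys = (
        emulate_cohort(TABLE_ANCHORS, seed=s_phys, n_subjects=n_subjects)
        if use_cohort_physiology
        else None
    )
    dev = draw_subject_effects(truth, n_subjects, seed=s_dev)
    data = simulate_domain_observations(
        truth, dev, grid, form, seed=s_obs, physiologies=phys
    )
    return data, truth, dev


# ---------------------------------------------------------------------------
# Incremental-test trace generator
# ---------------------------------------------------------------------------

#: piecewise-linear ventilatory-equivalent anchors (dimensionless)
EQ_O2_BASE = 24.0
EQ_O2_PEAK = 38.0
EQ_CO2_BASE = 26.0
EQ_CO2_PEAK = 32.0
#: stage-mean V̇O₂ increase planted when the plateau flag is on, mL·kg⁻¹·min⁻¹
PLATEAU_TARGET = 1.0


def simulate_incremental_test(
    phys: SubjectPhysiology,
    protocol: ProtocolSpec | None = None,
    noise_scale: float = 0.03,
    seed: int | np.random.SeedSequence = 0,
    plateau: bool = True,
    rpe_final: float = 19.0,
) -> BreathTrace:
    """Generate a 1-Hz incremental-test trace with planted VT breakpoints.

    HR rises monotonically to hr_peak.  V̇E/V̇O₂ is piecewise linear in
    time with a single upward slope change where HR crosses vt1_hr while
    V̇E/V̇CO₂ stays flat; V̇E/V̇CO₂ has its first upward slope change where
    HR crosses vt2_hr.  V̇O₂ flattens over the final two stages when the
    plateau flag is on.  Multiplicative Gaussian noise of SD ``noise_scale``
    is applied independently to the V̇O₂, V̇CO₂ and V̇E samples (breath-
    by-breath variability); HR is left smooth.
    """
    protocol = protocol or ProtocolSpec()
    rng = np.random.default_rng(seed)
    n_stages = max(
        int(round((phys.peak_speed_kmh - protocol.warmup_speed_kmh) / protocol.increment_kmh)),
        3,
    )
    t_w = protocol.warmup_duration_s
    T = int(t_w + n_stages * protocol.stage_duration_s)
    t = np.arange(T, dtype=float)

    speed = np.where(
        t < t_w,
        protocol.warmup_speed_kmh,
        protocol.warmup_speed_kmh
        + protocol.increment_kmh * (np.floor((t - t_w) / protocol.stage_duration_s) + 1),
    )

    # HR: linear ramp during warm-up, then linear to hr_peak at exhaustion
    hr = np.where(
        t < t_w,
        0.45 * phys.hr_peak + (phys.hr_at_warmup_end - 0.45 * phys.hr_peak) * t / t_w,
        phys.hr_at_warmup_end
        + (phys.hr_peak - phys.hr_at_warmup_end) * (t - t_w) / (T - 1 - t_w),
    )
    if not (hr[int(t_w)] < phys.vt1_hr < phys.vt2_hr < hr[-1] + 1e-9):
        raise InvalidParameterError("VT thresholds outside the HR trajectory")
    inc_slope = (phys.hr_peak - phys.hr_at_warmup_end) / (T - 1 - t_w)
    t_vt1 = t_w + (phys.vt1_hr - phys.hr_at_warmup_end) / inc_slope
    t_vt2 = t_w + (phys.vt2_hr - phys.hr_at_warmup_end) / inc_slope

    # V̇O₂ (mL/min): ramp, then reduced slope over the final two stages
    vp = phys.vo2_peak_ml_min
    v0 = 0.40 * vp
    vo2 = np.empty(T)
    vo2[t < t_w] = 0.35 * vp + (v0 - 0.35 * vp) * t[t < t_w] / t_w
    if plateau:
        t_fl = T - 2 * protocol.stage_duration_s  # flattening onset
        s2 = (PLATEAU_TARGET * phys.body_mass_kg) / protocol.stage_duration_s
        v_fl = vp - 2 * protocol.stage_duration_s * s2
        s1 = (v_fl - v0) / (t_fl - t_w)
        inc = t >= t_w
        vo2[inc] = np.where(
            t[inc] < t_fl,
            v0 + s1 * (t[inc] - t_w),
            v_fl + s2 * (t[inc] - t_fl),
        )
    else:
        vo2[t >= t_w] = v0 + (vp - v0) * (t[t >= t_w] - t_w) / (T - 1 - t_w)

    # ventilatory equivalents: flat until the planted threshold, then linear
    eq_o2 = np.where(
        t < t_vt1,
        EQ_O2_BASE,
        EQ_O2_BASE + (EQ_O2_PEAK - EQ_O2_BASE) * (t - t_vt1) / max(T - 1 - t_vt1, 1.0),
    )
    eq_co2 = np.where(
        t < t_vt2,
        EQ_CO2_BASE,
        EQ_CO2_BASE + (EQ_CO2_PEAK - EQ_CO2_BASE) * (t - t_vt2) / max(T - 1 - t_vt2, 1.0),
    )

    ve = eq_o2 * vo2 / 1000.0  # L/min
    vco2 = 1000.0 * ve / eq_co2  # mL/min

    if noise_scale > 0:
        vo2 = vo2 * (1 + noise_scale * rng.standard_normal(T))
        vco2 = vco2 * (1 + noise_scale * rng.standard_normal(T))
        ve = ve * (1 + noise_scale * rng.standard_normal(T))
        vo2, vco2, ve = (np.maximum(x, 1e-6) for x in (vo2, vco2, ve))

    samples = pd.DataFrame({
        "time_s": t,
        "speed_kmh": speed,
        "vo2_ml_min": vo2,
        "vco2_ml_min": vco2,
        "ve_l_min": ve,
        "hr_bpm": hr,
    })
    bin_of = lambda tt: int(round(tt / 15.0 - 0.5))  # bin whose center is nearest
    return BreathTrace(
        subject_id=phys.subject_id,
        samples=samples,
        body_mass_kg=phys.body_mass_kg,
        age_yr=phys.age_yr,
        rpe_final=rpe_final,
        truth={
            "t_vt1": float(t_vt1),
            "t_vt2": float(t_vt2),
            "vt1_bin": bin_of(t_vt1),
            "vt2_bin": bin_of(t_vt2),
            "warmup_bins": int(t_w // 15),
            "n_stages": n_stages,
            "plateau": plateau,
        },
    )
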