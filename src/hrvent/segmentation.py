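"""Reduction and segmentation of incremental cardiopulmonary exercise tests.

Breath-by-breath traces are reduced to 15-s bin means; ventilatory
equivalents (V̇E/V̇O₂, V̇E/V̇CO₂) are computed from the bin means and used
to locate the two ventilatory thresholds with a deterministic two-segment
piecewise-linear (hinge) least-squares breakpoint search:

* VT1 — earliest/best breakpoint in V̇E/V̇O₂ with an upward slope change
  while the local V̇E/V̇CO₂ slope stays flat;
* VT2 — first upward breakpoint in V̇E/V̇CO₂ (after VT1 when supplied).

The original determinations were made visually by blinded investigators;
the deterministic search here is a reproducible surrogate, and manual
thresholds can always be supplied downstream instead.  Bins at or after a
threshold bin belong to the higher intensity domain (half-open intervals,
consistent with "first abrupt increase").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BIN_WIDTH_S = 15.0
#: V̇O₂ plateau criterion between the last two stages, mL·kg⁻¹·min⁻¹
PLATEAU_DELTA = 2.1
RER_CRITERION = 1.1
HR_CRITERION_FRACTION = 0.9
RPE_CRITERION = 19

TRACE_COLUMNS = ["time_s", "speed_kmh", "vo2_ml_min", "vco2_ml_min", "ve_l_min", "hr_bpm"]


class ThresholdNotFoundError(RuntimeError):
    """No breakpoint satisfying the detection conditions exists."""


@dataclass
class BreathTrace:
    """One subject's raw incremental-test samples plus metadata."""

    subject_id: str
    samples: pd.DataFrame  # TRACE_COLUMNS
    body_mass_kg: float | None = None
    age_yr: float | None = None
    rpe_final: float | None = None
    truth: dict = field(default_factory=dict)  # generator-planted ground truth

    def __post_init__(self) -> None:
        missing = [c for c in TRACE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"trace missing columns: {missing}")
        t = self.samples["time_s"].to_numpy(dtype=float)
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        for c in ("vo2_ml_min", "vco2_ml_min", "ve_l_min"):
            if len(t) and np.any(self.samples[c].to_numpy(dtype=float) <= 0):
                raise ValueError(f"{c} must be positive")
        hr = self.samples["hr_bpm"].to_numpy(dtype=float)
        if len(t) and np.any((hr < 30) | (hr > 230)):
            raise ValueError("hr_bpm outside [30, 230]")


@dataclass
class BinnedSeries:
    """15-s bin means with ventilatory equivalents and optional domain labels."""

    bins: pd.DataFrame  # bin_start_s, speed_kmh, vo2_ml_min, vco2_ml_min,
    #                     ve_l_min, hr_bpm, eq_o2, eq_co2, n_samples[, domain]
    subject_id: str | None = None

    def __len__(self) -> int:
        return len(self.bins)


@dataclass
class ThresholdPoint:
    bin_index: int
    hr_bpm: float
    speed_kmh: float
    ve_l_min: float
    vo2_ml_min: float


@dataclass
class ThresholdSet:
    vt1: ThresholdPoint | None = None
    vt2: ThresholdPoint | None = None

    def __post_init__(self) -> None:
        if self.vt1 is not None and self.vt2 is not None:
            if not (self.vt1.bin_index < self.vt2.bin_index):
                raise ValueError("vt1 bin must precede vt2 bin")
            if not (self.vt1.hr_bpm < self.vt2.hr_bpm):
                raise ValueError("vt1 HR must be below vt2 HR")


@dataclass
class MaxTestVerdict:
    plateau: bool
    rer_criterion: bool
    hr_criterion: bool
    rpe_criterion: bool

    @property
    def accepted(self) -> bool:
        secondary = sum([self.rer_criterion, self.hr_criterion, self.rpe_criterion])
        return self.plateau or secondary >= 2


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------


def bin_15s(trace: BreathTrace) -> BinnedSeries:
    """Reduce a trace to 15-s means; a trailing partial bin is discarded.

    Bin values are arithmetic means of all samples with
    bin_start <= time < bin_start + 15; the ventilatory equivalents are
    ratios of the bin means (V̇E in L·min⁻¹, V̇O₂/V̇CO₂ in mL·min⁻¹,
    scaled to a dimensionless ratio).
    """
    df = trace.samples
    if not len(df):
        raise ValueError("empty trace")
    t = df["time_s"].to_numpy(dtype=float)
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    duration = t[-1] - t[0] + dt
    n_bins = int(np.floor(duration / BIN_WIDTH_S + 1e-9))
    if n_bins < 1:
        raise ValueError("trace shorter than one full 15-s bin")
    idx = np.floor((t - t[0]) / BIN_WIDTH_S).astype(int)
    keep = idx < n_bins
    g = df.loc[keep].groupby(idx[keep])
    means = g[["speed_kmh", "vo2_ml_min", "vco2_ml_min", "ve_l_min", "hr_bpm"]].mean()
    out = means.reset_index(drop=True)
    out.insert(0, "bin_start_s", t[0] + BIN_WIDTH_S * np.arange(len(out)))
    out["eq_o2"] = out["ve_l_min"] * 1000.0 / out["vo2_ml_min"]
    out["eq_co2"] = out["ve_l_min"] * 1000.0 / out["vco2_ml_min"]
    out["n_samples"] = g.size().to_numpy()
    return BinnedSeries(bins=out, subject_id=trace.subject_id)


# ---------------------------------------------------------------------------
# Maximal-test criteria
# ---------------------------------------------------------------------------


def assess_max_criteria(
    binned: BinnedSeries,
    age: float,
    body_mass: float | None = None,
    rpe_final: float | None = None,
    stage_duration_s: float = 60.0,
    warmup_duration_s: float = 0.0,
) -> MaxTestVerdict:
    """Apply the V̇O₂max plateau criterion and the secondary criteria.

    Plateau: increase in V̇O₂ < 2.1 mL·kg⁻¹·min⁻¹ between the mean values
    of the last two complete stages.  Secondary: max bin RER > 1.1, max bin
    HR >= 90% of (220 - age), and final RPE >= 19 (missing RPE counts as
    not met).  The test is accepted as maximal iff the plateau criterion or
    at least two secondary criteria hold.
    """
    df = binned.bins
    bins_per_stage = int(round(stage_duration_s / BIN_WIDTH_S))
    work = df[df["bin_start_s"] >= warmup_duration_s - 1e-9]
    n_stages = len(work) // bins_per_stage
    if n_stages < 2:
        raise ValueError("need at least two complete stages")
    if body_mass is None:
        raise ValueError("body_mass required for the plateau criterion")
    vo2 = work["vo2_ml_min"].to_numpy(dtype=float)[: n_stages * bins_per_stage]
    stage_means = vo2.reshape(n_stages, bins_per_stage).mean(axis=1)
    delta = (stage_means[-1] - stage_means[-2]) / body_mass
    plateau = bool(delta < PLATEAU_DELTA)
    rer = df["vco2_ml_min"] / df["vo2_ml_min"]
    rer_crit = bool(rer.max() > RER_CRITERION)
    hr_crit = bool(df["hr_bpm"].max() >= HR_CRITERION_FRACTION * (220.0 - age))
    rpe_crit = bool(rpe_final is not None and rpe_final >= RPE_CRITERION)
    return MaxTestVerdict(plateau, rer_crit, hr_crit, rpe_crit)


# ---------------------------------------------------------------------------
# Breakpoint detection
# ---------------------------------------------------------------------------

MIN_SEGMENT_BINS = 3
#: minimum hinge-slope increase treated as a real breakpoint (eq units/bin)
MIN_SLOPE_INCREASE = 1e-6
#: VT1 flatness condition: local eq_co2 slope <= this fraction of the
#: post-break eq_o2 slope
FLATNESS_FRACTION = 0.10


def _hinge_fits(yv: np.ndarray):
    """RSS and coefficients of continuous two-segment fits at every candidate
    interior breakpoint (>= MIN_SEGMENT_BINS bins per segment)."""
    n = yv.size
    x = np.arange(n, dtype=float)
    fits = []
    for c in range(MIN_SEGMENT_BINS, n - MIN_SEGMENT_BINS + 1):
        basis = np.column_stack([np.ones(n), x, np.maximum(x - c, 0.0)])
        coef, *_ = np.linalg.lstsq(basis, yv, rcond=None)
        rss = float(np.sum((yv - basis @ coef) ** 2))
        fits.append((c, rss, coef))
    return fits


def _local_slope(yv: np.ndarray, c: int, halfwidth: int = 1) -> float:
    lo, hi = max(c - halfwidth, 0), min(c + halfwidth + 1, yv.size)
    xs = np.arange(lo, hi, dtype=float)
    return float(np.polyfit(xs, yv[lo:hi], 1)[0])


def _window_slice(binned: BinnedSeries, search_window) -> tuple[int, int]:
    n = len(binned)
    if search_window is None:
        return 0, n
    lo, hi = search_window
    lo = int(max(lo, 0))
    hi = int(min(hi if hi is not None else n, n))
    return lo, hi


def _threshold_point(binned: BinnedSeries, bin_index: int) -> ThresholdPoint:
    row = binned.bins.iloc[bin_index]
    return ThresholdPoint(
        bin_index=int(bin_index),
        hr_bpm=float(row["hr_bpm"]),
        speed_kmh=float(row["speed_kmh"]),
        ve_l_min=float(row["ve_l_min"]),
        vo2_ml_min=float(row["vo2_ml_min"]),
    )


def detect_vt1(
    binned: BinnedSeries,
    search_window: tuple[int, int | None] | None = None,
    flatness_fraction: float = FLATNESS_FRACTION,
) -> ThresholdPoint:
    """Locate VT1: the breakpoint in V̇E/V̇O₂ with minimal two-segment RSS,
    an upward slope change, and a locally flat V̇E/V̇CO₂ (3-bin window)."""
    lo, hi = _window_slice(binned, search_window)
    eq_o2 = binned.bins["eq_o2"].to_numpy(dtype=float)[lo:hi]
    eq_co2 = binned.bins["eq_co2"].to_numpy(dtype=float)[lo:hi]
    if eq_o2.size < 2 * MIN_SEGMENT_BINS:
        raise ThresholdNotFoundError("search window too short for two segments")
    best = None
    for c, rss, coef in _hinge_fits(eq_o2):
        slope_increase = coef[2]
        if slope_increase <= MIN_SLOPE_INCREASE:
            continue
        post_slope = coef[1] + coef[2]
        if post_slope <= 0:
            continue
        if _local_slope(eq_co2, c) > flatness_fraction * post_slope:
            continue
        if best is None or rss < best[1] - 1e-12:
            best = (c, rss)
    if best is None:
        raise ThresholdNotFoundError("no VT1 breakpoint satisfies the conditions")
    return _threshold_point(binned, lo + best[0])


def detect_vt2(
    binned: BinnedSeries,
    search_window: tuple[int, int | None] | None = None,
    vt1: ThresholdPoint | None = None,
) -> ThresholdPoint:
    """Locate VT2: the first upward breakpoint in V̇E/V̇CO₂ (minimal RSS),
    required to fall after VT1 when one is supplied."""
    lo, hi = _window_slice(binned, search_window)
    eq_co2 = binned.bins["eq_co2"].to_numpy(dtype=float)[lo:hi]
    if eq_co2.size < 2 * MIN_SEGMENT_BINS:
        raise ThresholdNotFoundError("search window too short for two segments")
    best = None
    for c, rss, coef in _hinge_fits(eq_co2):
        if coef[2] <= MIN_SLOPE_INCREASE:
            continue
        if best is None or rss < best[1] - 1e-12:
            best = (c, rss)
    if best is None:
        raise ThresholdNotFoundError("no VT2 breakpoint satisfies the conditions")
    bin_index = lo + best[0]
    if vt1 is not None and bin_index <= vt1.bin_index:
        raise ThresholdNotFoundError(
            f"VT2 candidate (bin {bin_index}) not after VT1 (bin {vt1.bin_index})"
        )
    return _threshold_point(binned, bin_index)


def detect_thresholds(
    binned: BinnedSeries,
    warmup_duration_s: float = 0.0,
) -> ThresholdSet:
    """Convenience pipeline: exclude warm-up bins, detect VT1 then VT2."""
    start = int(np.searchsorted(
        binned.bins["bin_start_s"].to_numpy(dtype=float), warmup_duration_s - 1e-9
    ))
    window = (start, None)
    vt1 = detect_vt1(binned, window)
    # VT2 is searched over the same window (V̇E/V̇CO₂ is flat through VT1,
    # so the longer pre-segment stabilizes the fit); ordering is enforced.
    vt2 = detect_vt2(binned, window, vt1=vt1)
    return ThresholdSet(vt1=vt1, vt2=vt2)


# ---------------------------------------------------------------------------
# Domain labelling
# ---------------------------------------------------------------------------


def label_domains(
    binned: BinnedSeries,
    thresholds: ThresholdSet,
    warmup_duration_s: float = 0.0,
) -> BinnedSeries:
    """Label bins moderate/heavy/severe; the threshold bin itself belongs to
    the higher domain.  Warm-up bins get a null label."""
    if thresholds.vt1 is None or thresholds.vt2 is None:
        raise ValueError("both thresholds required")
    df = binned.bins.copy()
    idx = np.arange(len(df))
    domain = np.where(
        idx < thresholds.vt1.bin_index,
        "moderate",
        np.where(idx < thresholds.vt2.bin_index, "heavy", "severe"),
    ).astype(object)
    warm = df["bin_start_s"].to_numpy(dtype=float) < warmup_duration_s - 1e-9
    domain[warm] = None
    df["domain"] = domain
    return BinnedSeries(bins=df, subject_id=binned.subject_id)
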