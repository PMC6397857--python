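"""Incremental-ramp-test indexes: VO2max, GET, Δ50% and peak values.

The derived quantities follow the standard exercise-testing conventions:

* **VO2max** — highest 15-s rolling mean of VO2; a plateau is declared when,
  within some 60-s window during the ramp, the mean of the second half
  exceeds the mean of the first half by less than 150 mL·min⁻¹.
* **GET** — V-slope breakpoint: a continuous two-segment linear regression of
  VCO2 on VO2, breakpoint chosen among observed VO2 values in the central
  80% of the range by minimum total SSE, subject to the upper slope being
  steeper than the lower.
* **Δ50%** — VO2 halfway between GET and VO2max; the corresponding work rate
  comes from inverting an OLS line of VO2 against instantaneous work rate
  over the ramp segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from .breath_io import BreathSeries, SessionMeta, ValidationError
from .preprocess import UniformSeries
from .synthetic_data import ramp_workload

__all__ = [
    "RampResult",
    "detect_vo2max",
    "detect_get_vslope",
    "compute_delta50",
    "workload_at_vo2",
    "vo2max_overshoot",
    "analyze_ramp",
    "round_half_up",
]

#: plateau rule: half-window mean rise below this over any 60-s ramp window
PLATEAU_RISE_LMIN = 0.150


class ThresholdError(ValueError):
    """No V-slope breakpoint satisfying the slope constraint."""


def round_half_up(x: float, decimals: int) -> float:
    """Decimal half-up rounding (the convention of printed report tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RampResult:
    """All incremental-test outcomes for one participant."""

    vo2max: float            # L·min⁻¹
    plateau_found: bool
    wpeak: float             # W
    hrmax: float             # bpm
    get_vo2: float           # L·min⁻¹
    get_w: float             # W
    delta50_vo2: float       # L·min⁻¹
    delta50_w: float         # W
    regression: tuple[float, float, float]  # intercept (L·min⁻¹), slope (L·min⁻¹/W), r²

    def __post_init__(self) -> None:
        if not (self.get_vo2 < self.delta50_vo2 < self.vo2max):
            raise ValidationError("need GET VO2 < Δ50% VO2 < VO2max")


# ---------------------------------------------------------------------------

def detect_vo2max(
    series: UniformSeries, ramp_start: float = 0.0, plateau_skip: float = 30.0
) -> tuple[float, bool]:
    """VO2max by the 15-s rolling mean, with the 60-s plateau rule.

    ``series`` is a 1-s VO2 series; t = 0 marks the ramp start. The plateau
    test compares the two 30-s half-means of every 60-s window inside the
    ramp segment (work rate rising throughout), skipping the first
    ``plateau_skip`` s whose samples reflect the on-transient rather than
    stabilisation; a rise strictly below 0.150 L·min⁻¹ declares a plateau.
    Either way, VO2max is the maximum 15-s rolling mean over the ramp.
    """
    if series.dt != 1.0:
        raise ValidationError("detect_vo2max expects a 1-s series")
    m = series.t >= ramp_start
    t = series.t[m]
    v = series.values[m]
    if t.size < 60:
        raise ValidationError("ramp segment shorter than 60 s")

    win15 = np.lib.stride_tricks.sliding_window_view(v, 15).mean(axis=1)
    vo2max = float(win15.max())

    mp = t >= ramp_start + plateau_skip
    if np.count_nonzero(mp) < 60:
        raise ValidationError("ramp segment too short for the plateau scan")
    half = np.lib.stride_tricks.sliding_window_view(v[mp], 30).mean(axis=1)
    # rise between consecutive 30-s half-windows of each 60-s window
    rises = half[30:] - half[:-30]
    # strict comparison with a float guard: a ramp rising exactly at the
    # criterion rate is not a plateau
    plateau = bool(np.any(rises < PLATEAU_RISE_LMIN - 1e-9))
    return vo2max, plateau


def detect_get_vslope(vo2: UniformSeries, vco2: UniformSeries) -> float:
    """Gas-exchange threshold: V-slope two-segment regression breakpoint.

    Candidate breakpoints are the observed VO2 values inside the central 80%
    of the VO2 range; for each, VCO2 is regressed on [1, VO2, (VO2 − c)₊]
    (a continuous hinge), and the candidate minimising total SSE with a
    positive hinge coefficient (upper slope > lower slope) is returned.
    """
    common, iv, ic = np.intersect1d(vo2.t, vco2.t, return_indices=True)
    x = vo2.values[iv]
    y = vco2.values[ic]
    if x.size < 40:
        raise ValidationError(f"need >= 40 paired samples for V-slope, got {x.size}")

    x_lo, x_hi = float(x.min()), float(x.max())
    margin = 0.10 * (x_hi - x_lo)
    cands = np.unique(x[(x >= x_lo + margin) & (x <= x_hi - margin)])
    if cands.size == 0:
        raise ThresholdError("no candidate breakpoints in the central VO2 range")

    best_c, best_sse = None, np.inf
    for c in cands:
        hinge = np.maximum(x - c, 0.0)
        # need points on both sides to identify both slopes
        if np.count_nonzero(hinge > 0) < 3 or np.count_nonzero(x < c) < 3:
            continue
        design = np.column_stack((np.ones_like(x), x, hinge))
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        if coef[2] <= 0:  # upper slope must exceed lower slope
            continue
        resid = design @ coef - y
        sse = float(resid @ resid)
        if sse < best_sse:
            best_c, best_sse = float(c), sse
    if best_c is None:
        raise ThresholdError("no breakpoint with upper slope > lower slope")
    return best_c


def compute_delta50(get_vo2: float, vo2max: float) -> float:
    """VO2 target halfway between GET and VO2max."""
    if vo2max < get_vo2:
        raise ValidationError("vo2max must be >= get_vo2")
    return get_vo2 + 0.5 * (vo2max - get_vo2)


def workload_at_vo2(
    vo2: UniformSeries,
    meta: SessionMeta,
    target: float,
    skip_start: float = 30.0,
    skip_end: float = 15.0,
) -> float:
    """Invert the VO2/work-rate regression to find the work rate for a VO2.

    An OLS line of VO2 on instantaneous work rate is fitted over the ramp
    segment, excluding the first ``skip_start`` s (on-transient) and the last
    ``skip_end`` s (end-test instability). Targets outside the fitted VO2
    range raise an extrapolation warning but are still inverted.
    """
    t_hi = float(vo2.t[-1])
    m = (vo2.t >= skip_start) & (vo2.t <= t_hi - skip_end)
    if np.count_nonzero(m) < 4:
        raise ValidationError("too few ramp samples for the VO2/intensity regression")
    w = np.asarray(ramp_workload(vo2.t[m], meta), dtype=float)
    v = vo2.values[m]
    slope, intercept = np.polyfit(w, v, 1)
    if slope <= 1e-9:  # physiological gains are ~0.01 L·min⁻¹/W
        raise ValidationError("non-positive VO2/intensity slope")
    if not (v.min() <= target <= v.max()):
        warnings.warn("target VO2 outside the fitted range; extrapolating", stacklevel=2)
    return float((target - intercept) / slope)


def vo2max_overshoot(vo2_end: float, predicted: float) -> float:
    """Percent excess of end-exercise VO2 over the ramp-predicted target."""
    if predicted <= 0:
        raise ValidationError("predicted VO2 must be positive")
    return 100.0 * (vo2_end - predicted) / predicted


def _regression_stats(vo2: UniformSeries, meta: SessionMeta,
                      skip_start: float = 30.0, skip_end: float = 15.0):
    t_hi = float(vo2.t[-1])
    m = (vo2.t >= skip_start) & (vo2.t <= t_hi - skip_end)
    w = np.asarray(ramp_workload(vo2.t[m], meta), dtype=float)
    v = vo2.values[m]
    slope, intercept = np.polyfit(w, v, 1)
    pred = intercept + slope * w
    sst = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - float(np.sum((v - pred) ** 2)) / sst if sst > 0 else 1.0
    return float(intercept), float(slope), float(r2)


def analyze_ramp(
    series: BreathSeries,
    vo2_1s: UniformSeries,
    vo2_5s: UniformSeries,
    vco2_5s: UniformSeries,
) -> RampResult:
    """Derive all ramp indexes from the cleaned series of one test.

    ``series`` supplies peak work rate and HR (highest observed values);
    the 1-s VO2 series feeds the VO2max/plateau scan and the 5-s binned
    series the V-slope and the VO2/intensity regression.
    """
    meta = series.meta
    vo2max, plateau = detect_vo2max(vo2_1s)
    get_vo2 = detect_get_vslope(vo2_5s, vco2_5s)
    delta50 = compute_delta50(get_vo2, vo2max)
    get_w = workload_at_vo2(vo2_5s, meta, get_vo2)
    delta50_w = workload_at_vo2(vo2_5s, meta, delta50)

    t_rel = series.t - meta.transition_onset
    ex = t_rel >= 0
    wpeak = float(np.max(np.asarray(ramp_workload(t_rel[ex], meta), dtype=float)))
    hr_ex = series.hr[ex]
    hrmax = float(np.nanmax(hr_ex)) if np.any(np.isfinite(hr_ex)) else float("nan")

    return RampResult(
        vo2max=vo2max,
        plateau_found=plateau,
        wpeak=wpeak,
        hrmax=hrmax,
        get_vo2=get_vo2,
        get_w=get_w,
        delta50_vo2=delta50,
        delta50_w=delta50_w,
        regression=_regression_stats(vo2_5s, meta),
    )
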