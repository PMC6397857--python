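"""Exponential modelling of on-transition kinetics.

Three model fits are provided:

* **Phase II** — the delayed mono-exponential
  ``VO2(t) = VO2_base + Ap·(1 − exp(−(t − TD)/τ))`` for t ≥ TD, with the
  baseline *fixed* at the measured last-minute 20-W mean and (Ap, τ, TD)
  estimated by multi-start nonlinear least squares.
* **Slow component** — the phase-II fit is repeated over candidate windows
  [20 s, t_end] with t_end on a 5-s grid; the window whose τ has the
  narrowest 95% confidence interval marks the slow-component onset, and the
  amplitude is ``As = VO2_end − (VO2_base + Ap)`` with VO2_end the mean over
  the last 15 s of exercise.
* **Mean response time** — a delay-free mono-exponential
  ``y(t) = base + A·(1 − exp(−t/MRT))`` fitted from onset to a fixed end
  point (480 s for VO2, 180 s for HR and O2 pulse), all parameters free.

Confidence intervals come from the linearised parameter covariance at the
least-squares solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .breath_io import ValidationError
from .preprocess import UniformSeries, CARDIO_PHASE_S, baseline_mean

__all__ = [
    "PhaseIIFit",
    "SlowComponent",
    "MRTFit",
    "KineticsResult",
    "FitError",
    "fit_phase2",
    "detect_slow_component",
    "fit_mrt",
    "compute_o2_pulse",
    "analyze_condition",
]

#: identifiability floor for exponential amplitudes, L·min⁻¹ (or channel units)
MIN_AMPLITUDE = 0.05

PHASE2_BOUNDS = ((0.0, 1e-3, 0.0), (5.0, 200.0, 35.0))  # Ap, tau, TD
TAU_STARTS = (20.0, 40.0, 60.0, 90.0)
TD_STARTS = (0.0, 10.0, 20.0)

# slow-component window selection (see detect_slow_component)
FORECAST_HORIZON_S = 30.0
FORECAST_Z_THRESHOLD = 2.5
FORECAST_MIN_EXCESS = 0.01   # L·min⁻¹ floor: z alone is scale-free
FORECAST_BACKOFF_S = 10.0
MIN_STABLE_WINDOW_END_S = 90.0


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge from every start."""


@dataclass
class PhaseIIFit:
    """Phase-II parameters with uncertainty and diagnostics."""

    vo2_base: float          # fixed constraint, L·min⁻¹
    ap: float                # amplitude, L·min⁻¹
    tau_p: float             # time constant, s
    td_p: float              # time delay, s
    ci_tau: tuple[float, float]  # 95% CI for tau, s
    r2: float
    rmse: float              # L·min⁻¹
    fit_window: tuple[float, float]
    n_samples: int
    identifiable: bool = True

    @property
    def ci_width(self) -> float:
        return self.ci_tau[1] - self.ci_tau[0]


@dataclass
class SlowComponent:
    """Slow-component onset/amplitude and the per-candidate criteria trace."""

    onset: float             # s (selected fit-window end)
    a_s: float               # amplitude, L·min⁻¹ (0 when not detected)
    vo2_end: float           # mean over last 15 s of exercise, L·min⁻¹
    detected: bool
    criteria_trace: list[dict] = field(default_factory=list)


@dataclass
class MRTFit:
    """Delay-free mono-exponential summary of overall kinetics."""

    base: float              # channel units
    amplitude: float         # channel units
    mrt: float               # s
    r2: float
    end_time: float          # s
    identifiable: bool = True


@dataclass
class KineticsResult:
    """Per-condition bundle of all kinetic outcomes."""

    phase2: PhaseIIFit
    slow: SlowComponent
    mrt_vo2: MRTFit
    mrt_hr: MRTFit
    mrt_o2pulse: MRTFit
    hr_base: float           # bpm
    o2pulse_base: float      # mL·beat⁻¹

    def variables(self) -> dict[str, float]:
        """Flat mapping of the reportable outcome variables."""
        return {
            "vo2_base": self.phase2.vo2_base,
            "Ap": self.phase2.ap,
            "tau_p": self.phase2.tau_p,
            "TD_p": self.phase2.td_p,
            "As": self.slow.a_s,
            "A_t": self.slow.vo2_end,
            "MRT_vo2": self.mrt_vo2.mrt,
            "HR_base": self.hr_base,
            "A_180s_hr": self.mrt_hr.amplitude,
            "MRT_180s_hr": self.mrt_hr.mrt,
            "o2pulse_base": self.o2pulse_base,
            "A_180s_o2pulse": self.mrt_o2pulse.amplitude,
            "MRT_180s_o2pulse": self.mrt_o2pulse.mrt,
        }


# ---------------------------------------------------------------------------
# model functions and jacobians
# ---------------------------------------------------------------------------

def _phase2_model(t: np.ndarray, ap: float, tau: float, td: float, base: float) -> np.ndarray:
    u = np.clip((t - td) / tau, 0.0, 700.0)
    return base + ap * (1.0 - np.exp(-u))


def _phase2_jac(t: np.ndarray, ap: float, tau: float, td: float) -> np.ndarray:
    u = (t - td) / tau
    on = u > 0
    u = np.clip(u, 0.0, 700.0)
    e = np.exp(-u)
    j = np.zeros((t.size, 3))
    j[:, 0] = 1.0 - e
    j[on, 1] = -ap * e[on] * u[on] / tau
    j[on, 2] = -ap * e[on] / tau
    return j


def _mrt_model(t: np.ndarray, base: float, amp: float, tau: float) -> np.ndarray:
    u = np.clip(t / tau, None, 700.0)
    return base + amp * (1.0 - np.exp(-u))


def _mrt_jac(t: np.ndarray, base: float, amp: float, tau: float) -> np.ndarray:
    u = np.clip(t / tau, None, 700.0)
    e = np.exp(-u)
    j = np.empty((t.size, 3))
    j[:, 0] = 1.0
    j[:, 1] = 1.0 - e
    j[:, 2] = -amp * e * u / tau
    return j


def _least_squares(residual, jac, x0, bounds):
    x0 = np.clip(np.asarray(x0, dtype=float), bounds[0], bounds[1])
    return optimize.least_squares(residual, x0, jac=jac, bounds=bounds, method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)


def _tau_ci(jacobian: np.ndarray, residuals: np.ndarray, tau_index: int) -> float:
    """95% CI half-width for tau from the linearised covariance; inf if singular."""
    n, p = jacobian.shape
    dof = n - p
    if dof <= 0:
        return float("inf")
    sse = float(residuals @ residuals)
    jtj = jacobian.T @ jacobian
    try:
        cov = np.linalg.inv(jtj) * (sse / dof)
    except np.linalg.LinAlgError:
        return float("inf")
    var = cov[tau_index, tau_index]
    if not np.isfinite(var) or var < 0:
        return float("inf")
    return float(stats.t.ppf(0.975, dof) * np.sqrt(var))


def _goodness(y: np.ndarray, resid: np.ndarray) -> tuple[float, float]:
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return float(np.clip(r2, 0.0, 1.0)), float(np.sqrt(sse / y.size))


# ---------------------------------------------------------------------------
# phase II
# ---------------------------------------------------------------------------

def fit_phase2(
    series: UniformSeries,
    baseline: float,
    window: tuple[float, float],
    extra_starts: tuple[tuple[float, float, float], ...] = (),
    min_samples: int = 10,
    full_grid: bool = True,
) -> PhaseIIFit:
    """Fit the delayed mono-exponential with the baseline held fixed.

    ``window`` bounds (s, inclusive) select the samples entering the fit; it
    must start at or after the cardiodynamic phase. Multi-start least squares
    over a τ × TD grid (plus any ``extra_starts`` of (Ap, τ, TD)) guards
    against local minima; ties in SSE resolve to the smallest τ.
    """
    lo, hi = window
    if lo < CARDIO_PHASE_S:
        raise ValidationError("phase-II window must start at or after 20 s")
    sel = (series.t >= lo) & (series.t <= hi)
    t = series.t[sel]
    y = series.values[sel]
    if t.size < min_samples:
        raise ValidationError(f"only {t.size} samples in window [{lo}, {hi}]; need >= {min_samples}")

    def residual(x):
        return _phase2_model(t, *x, base=baseline) - y

    def jac(x):
        return _phase2_jac(t, *x)

    ap0 = float(np.clip(np.max(y) - baseline, MIN_AMPLITUDE, 5.0))
    if full_grid:
        starts = [(ap0, tau, td) for tau in TAU_STARTS for td in TD_STARTS]
    else:
        # warm-started scan: one generic start is enough next to the carryover
        starts = [(ap0, 50.0, 5.0)]
    starts.extend(extra_starts)

    best = None
    for x0 in starts:
        try:
            res = _least_squares(residual, jac, x0, PHASE2_BOUNDS)
        except Exception:
            continue
        if not res.success:
            continue
        sse = 2.0 * res.cost
        if best is None or sse < best_sse * (1 - 1e-12) or (
            abs(sse - best_sse) <= 1e-12 * max(best_sse, 1e-300) and res.x[1] < best.x[1]
        ):
            best, best_sse = res, sse
    if best is None:
        raise FitError(f"phase-II fit did not converge in window [{lo}, {hi}]")

    ap, tau, td = (float(v) for v in best.x)
    resid = best.fun
    half = _tau_ci(_phase2_jac(t, ap, tau, td), resid, tau_index=1)
    r2, rmse = _goodness(y, resid)
    return PhaseIIFit(
        vo2_base=float(baseline),
        ap=ap,
        tau_p=tau,
        td_p=td,
        ci_tau=(tau - half, tau + half),
        r2=r2,
        rmse=rmse,
        fit_window=(float(lo), float(hi)),
        n_samples=int(t.size),
        identifiable=ap >= MIN_AMPLITUDE,
    )


# ---------------------------------------------------------------------------
# slow component
# ---------------------------------------------------------------------------

def _first_sustained_minimum(widths: np.ndarray, lookahead: int = 4) -> int | None:
    """Index of the first CI width below its preceding and next ``lookahead``
    values (strictly); None when no such sustained local minimum exists."""
    n = widths.size
    for i in range(1, n - lookahead):
        w = widths[i]
        if not np.isfinite(w):
            continue
        if w < widths[i - 1] and np.all(w < widths[i + 1:i + 1 + lookahead]):
            return i
    return None

def detect_slow_component(
    series: UniformSeries,
    baseline: float,
    end_time: float = 480.0,
    grid: tuple[float, float, float] = (60.0, 420.0, 5.0),
) -> tuple[SlowComponent, PhaseIIFit]:
    """Locate the slow-component onset and compute its amplitude.

    Phase II is fitted over candidate windows [20, t_end] for t_end on the
    given (start, stop, step) grid. Three window-selection rules are applied
    in order of statistical power:

    1. **Residual-forecast breakpoint** (operative): each candidate fit
       predicts the 30 s beyond its window; the standardized mean forecast
       residual z(t_end) jumps once the slow component enters the horizon.
       The first t_end (from 90 s on, where fits are stable) with two
       consecutive z > 2.5 marks contamination inside (t_end, t_end+30];
       the fit window ends 10 s later — the last candidates that are still
       uncontaminated.
    2. **Narrowest-CI local minimum**: the CI of τ shrinks ~1/√n while the
       window is clean and inflates once contaminated; the first sustained
       local minimum of CI width (narrower than the previous and next four
       candidates) marks the onset.
    3. **Global narrowest CI**, ties resolved toward the latest window —
       the mono-exponential case, where the CI keeps narrowing to the end.

    The per-candidate diagnostics (CI width, forecast z, Ap, τ, TD, r² —
    the systematic-rise criteria) are recorded in ``criteria_trace``.

    Returns the slow component together with the phase-II fit of the chosen
    window. Detection requires As > 0.05 L·min⁻¹; otherwise As is 0.
    """
    t_max = float(series.t[-1])
    if t_max < 240.0:
        raise ValidationError("exercise span must reach at least 240 s")

    end_sel = series.t >= (end_time - 15.0)
    if not np.any(end_sel):
        raise ValidationError("no samples in the final 15 s of exercise")
    vo2_end = float(series.values[end_sel].mean())

    lo, hi, step = grid
    candidates = np.arange(lo, min(hi, t_max) + 1e-9, step)
    trace: list[dict] = []
    fits: list[PhaseIIFit] = []
    warm: tuple[tuple[float, float, float], ...] = ()
    rmses: list[float] = []
    for t_end in candidates:
        try:
            f = fit_phase2(
                series,
                baseline,
                (CARDIO_PHASE_S, float(t_end)),
                extra_starts=warm,
                full_grid=not warm,
            )
        except (ValidationError, FitError):
            continue
        warm = ((f.ap, f.tau_p, f.td_p),)
        rmses.append(f.rmse)
        # standardized mean forecast residual over the next 30 s; the pooled
        # (running-median) rmse keeps short-window noise out of the scale
        ahead = (series.t > t_end) & (series.t <= t_end + FORECAST_HORIZON_S)
        if np.count_nonzero(ahead) >= 3:
            pred = _phase2_model(series.t[ahead], f.ap, f.tau_p, f.td_p, base=baseline)
            resid = series.values[ahead] - pred
            scale = max(float(np.median(rmses)), 1e-12)
            excess = float(resid.mean())
            z = float(excess / (scale / np.sqrt(resid.size)))
            if excess <= FORECAST_MIN_EXCESS:
                z = min(z, 0.0)  # physically negligible forecast excess
        else:
            z = float("nan")
        fits.append(f)
        trace.append(
            {
                "t_end": float(t_end),
                "ci_width": f.ci_width,
                "forecast_z": z,
                "Ap": f.ap,
                "tau": f.tau_p,
                "TD": f.td_p,
                "r2": f.r2,
            }
        )
    if not fits:
        raise FitError("no candidate window produced a phase-II fit")

    t_ends = np.array([r["t_end"] for r in trace])
    widths = np.array([f.ci_width for f in fits])
    zs = np.array([r["forecast_z"] for r in trace])
    stable = np.flatnonzero(t_ends >= MIN_STABLE_WINDOW_END_S)

    chosen = None
    # rule 1: residual-forecast breakpoint
    for a, b in zip(stable, stable[1:]):
        if np.isfinite(zs[a]) and np.isfinite(zs[b]) and zs[a] > FORECAST_Z_THRESHOLD and zs[b] > FORECAST_Z_THRESHOLD:
            target = t_ends[a] + FORECAST_BACKOFF_S
            chosen = int(np.max(np.flatnonzero(t_ends <= target)))
            break
    # rule 2: first sustained local minimum of CI width
    if chosen is None and stable.size:
        local = _first_sustained_minimum(widths[stable], lookahead=4)
        if local is not None:
            chosen = int(stable[local])
    # rule 3: global narrowest CI, latest window on ties
    if chosen is None:
        w_min = float(np.min(widths))
        tol = 0.01 * w_min + 0.05
        chosen = int(np.max(np.flatnonzero(widths <= w_min + tol)))
    best = fits[chosen]

    # associativity matters: keep the exact expression of the amplitude
    # identity (vo2_end - base - Ap - As == 0, bit-exact)
    a_s = vo2_end - baseline - best.ap
    detected = a_s > MIN_AMPLITUDE
    slow = SlowComponent(
        onset=float(best.fit_window[1]),
        a_s=float(a_s) if detected else 0.0,
        vo2_end=vo2_end,
        detected=detected,
        criteria_trace=trace,
    )
    return slow, best


# ---------------------------------------------------------------------------
# mean response time
# ---------------------------------------------------------------------------

def fit_mrt(series: UniformSeries, end_time: float, min_samples: int = 8) -> MRTFit:
    """Fit the delay-free mono-exponential from onset to ``end_time``.

    All three parameters (base, amplitude, τ) are free; MRT is the fitted τ.
    Samples with 0 < t <= end_time enter the fit (the cleaned series already
    lacks the cardiodynamic seconds, which is immaterial to a delay-free
    model evaluated over its whole span).
    """
    sel = (series.t > 0) & (series.t <= end_time)
    t = series.t[sel]
    y = series.values[sel]
    if t.size < min_samples:
        raise ValidationError(f"only {t.size} samples up to {end_time} s; need >= {min_samples}")

    y_lo, y_hi = float(np.min(y)), float(np.max(y))
    rng_y = max(y_hi - y_lo, 1e-6)
    bounds = (
        np.array([max(y_lo - rng_y, 0.0), 0.0, 1e-3]),
        np.array([y_hi + rng_y, 3.0 * rng_y + 1e-6, 200.0]),
    )

    def residual(x):
        return _mrt_model(t, *x) - y

    def jac(x):
        return _mrt_jac(t, *x)

    best = None
    for tau0 in TAU_STARTS:
        x0 = (y_lo, rng_y, tau0)
        try:
            res = _least_squares(residual, jac, x0, bounds)
        except Exception:
            continue
        if not res.success:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError(f"MRT fit did not converge (end_time={end_time})")

    base, amp, tau = (float(v) for v in best.x)
    r2, _ = _goodness(y, best.fun)
    return MRTFit(
        base=base,
        amplitude=amp,
        mrt=tau,
        r2=r2,
        end_time=float(end_time),
        identifiable=amp >= MIN_AMPLITUDE,
    )


# ---------------------------------------------------------------------------
# O2 pulse and per-condition orchestration
# ---------------------------------------------------------------------------

def compute_o2_pulse(vo2: UniformSeries, hr: UniformSeries) -> UniformSeries:
    """Pointwise O2 pulse (mL·beat⁻¹) = 1000·VO2 / HR on the common grid."""
    common, iv, ih = np.intersect1d(vo2.t, hr.t, return_indices=True)
    if common.size == 0:
        raise ValidationError("VO2 and HR series do not overlap")
    hr_vals = hr.values[ih]
    bad = hr_vals <= 0
    if np.any(bad):
        raise ValidationError(f"non-positive HR at t={common[bad][0]:g} s")
    return UniformSeries(common, 1000.0 * vo2.values[iv] / hr_vals, vo2.dt, "o2pulse")


def analyze_condition(
    vo2: UniformSeries,
    hr: UniformSeries,
    baseline: float,
    end_time: float = 480.0,
    mrt_end_cardio: float = 180.0,
) -> KineticsResult:
    """Full kinetic analysis of one condition's cleaned, binned series.

    Runs slow-component detection (which embeds the phase-II fit), overall
    MRT of VO2 to end-exercise, and 180-s MRT fits of HR and O2 pulse, with
    HR/O2-pulse baselines averaged over the last pre-onset minute.
    """
    o2p = compute_o2_pulse(vo2, hr)
    slow, phase2 = detect_slow_component(vo2, baseline, end_time=end_time)
    return KineticsResult(
        phase2=phase2,
        slow=slow,
        mrt_vo2=fit_mrt(vo2, end_time),
        mrt_hr=fit_mrt(hr, mrt_end_cardio),
        mrt_o2pulse=fit_mrt(o2p, mrt_end_cardio),
        hr_base=baseline_mean(hr),
        o2pulse_base=baseline_mean(o2p),
    )
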