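"""Synthetic breath-by-breath gas-exchange recordings with known ground truth.

Two protocols are generated:

* **square-wave transitions** — 3 min of 20 W baseline pedalling followed by
  8 min at a heavy constant load, with a cardiodynamic bump in the first
  seconds, a delayed mono-exponential phase-II rise of VO2 and an optional
  delayed slow component, plus a delay-free mono-exponential HR response;
* **ramp tests** — 4 min at 20 W then a 30 W·min⁻¹ ramp, VO2 rising linearly
  with work rate (optionally saturating at a plateau) and VCO2 rising
  piecewise-linearly in VO2 with a slope break at the gas-exchange threshold.

Breath sampling is irregular: the inter-breath interval shrinks linearly from
its baseline value toward its minimum as VO2 rises, with multiplicative
jitter. Measurement noise is additive Gaussian per breath; sporadic
sigh/cough artifacts multiply isolated breaths by a fixed factor. Every
generator is a pure function of its explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict
from pathlib import Path
import json

import numpy as np

from .breath_io import BreathSeries, SessionMeta, ValidationError

__all__ = [
    "TruthParams",
    "NoiseParams",
    "RampTruth",
    "true_response",
    "true_hr_response",
    "simulate_transition",
    "simulate_ramp",
    "ramp_workload",
    "DEFAULT_TRUTH",
    "DEFAULT_NOISE",
    "DEFAULT_RAMP_TRUTH",
]


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth response parameters of a square-wave transition.

    Defaults reproduce a recreationally active adult cycling in the heavy
    domain: baseline VO2 1.08 L·min⁻¹, phase-II amplitude 2.07 L·min⁻¹ with a
    50.1 s time constant and 6.1 s delay, and a 0.22 L·min⁻¹ slow component
    emerging 120 s into exercise.
    """

    vo2_base: float = 1.08   # L·min⁻¹
    ap: float = 2.07         # phase-II amplitude, L·min⁻¹
    tau_p: float = 50.1      # phase-II time constant, s
    td_p: float = 6.1        # phase-II time delay, s
    a_s: float = 0.22        # slow-component amplitude, L·min⁻¹
    sc_onset: float = 120.0  # slow-component onset, s after exercise start
    sc_tau: float = 60.0     # slow-component time constant, s
    hr_base: float = 93.0    # bpm
    hr_amp: float = 61.0     # bpm
    hr_tau: float = 67.0     # s
    cardio_amp: float = 0.15  # cardiodynamic-phase bump, L·min⁻¹
    cardio_dur: float = 20.0  # s

    def __post_init__(self) -> None:
        if self.tau_p <= 0:
            raise ValidationError("tau_p must be positive")
        if self.a_s < 0:
            raise ValidationError("slow-component amplitude must be >= 0")
        if self.sc_onset <= self.td_p:
            raise ValidationError("sc_onset must exceed the phase-II delay")
        if self.sc_tau <= 0 or self.hr_tau <= 0:
            raise ValidationError("time constants must be positive")
        if self.cardio_dur > 20.0:
            raise ValidationError("cardiodynamic phase cannot exceed 20 s")


@dataclass(frozen=True)
class NoiseParams:
    """Measurement/sampling noise model for the breath-by-breath generators."""

    vo2_sd: float = 0.10             # additive Gaussian SD on VO2, L·min⁻¹
    hr_sd: float = 2.0               # additive Gaussian SD on HR, bpm
    breath_interval_base: float = 3.0  # inter-breath interval at baseline VO2, s
    breath_interval_min: float = 1.5   # inter-breath interval at peak VO2, s
    artifact_rate: float = 0.5       # sigh/cough spikes per minute
    artifact_scale: float = 1.8      # multiplicative spike factor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vo2_sd < 0 or self.hr_sd < 0 or self.artifact_rate < 0:
            raise ValidationError("noise magnitudes must be non-negative")
        if self.breath_interval_base <= 0 or self.breath_interval_min <= 0:
            raise ValidationError("breath intervals must be positive")
        if self.breath_interval_min > self.breath_interval_base:
            raise ValidationError("breath_interval_min must not exceed the baseline interval")
        if self.artifact_scale <= 1:
            raise ValidationError("artifact_scale must exceed 1")


@dataclass(frozen=True)
class RampTruth:
    """Ground truth of an incremental ramp test.

    VO2 rises linearly with work rate at ``gain`` L·min⁻¹ per W from
    ``vo2_rest`` (the true VO2 at 0 W), saturating at ``vo2max_cap`` when
    ``plateau`` is set. VCO2 is piecewise linear in VO2 with slope
    ``vco2_slope_below`` under the gas-exchange threshold and
    ``vco2_slope_below × slope_ratio_above_get`` above it.
    """

    vo2_rest: float = 0.5           # L·min⁻¹ at 0 W
    gain: float = 0.010             # L·min⁻¹ per W
    get_vo2: float = 2.03           # threshold VO2, L·min⁻¹
    slope_ratio_above_get: float = 1.4
    vo2max_cap: float = 3.48        # L·min⁻¹
    plateau: bool = False
    vco2_slope_below: float = 0.90
    hr_rest: float = 85.0           # bpm at 0 W
    hr_gain: float = 0.33           # bpm per W
    hr_max: float = 195.0           # bpm ceiling

    def __post_init__(self) -> None:
        if not (self.vo2_rest < self.get_vo2 < self.vo2max_cap):
            raise ValidationError("need vo2_rest < get_vo2 < vo2max_cap")
        if self.gain <= 0 or self.slope_ratio_above_get <= 1:
            raise ValidationError("gain must be > 0 and slope ratio > 1")


DEFAULT_TRUTH = TruthParams()
DEFAULT_NOISE = NoiseParams()
DEFAULT_RAMP_TRUTH = RampTruth()


# ---------------------------------------------------------------------------
# noiseless response curves
# ---------------------------------------------------------------------------

def true_response(t, p: TruthParams):
    """Noiseless VO2 (L·min⁻¹) at time ``t`` (s relative to exercise onset).

    Piecewise: baseline for t < 0; baseline plus a saturating cardiodynamic
    bump on [0, td_p); the delayed phase-II exponential for t >= td_p, with
    the slow-component exponential added from ``sc_onset`` onward.
    """
    scalar = np.isscalar(t) or getattr(t, "ndim", 0) == 0
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.full(t.shape, p.vo2_base)

    pre = (t >= 0) & (t < p.td_p)
    if np.any(pre):
        # fast-saturating bump standing in for the pulmonary-blood-flow phase
        tau_c = max(p.cardio_dur, 1e-9) / 4.0
        out[pre] = p.vo2_base + p.cardio_amp * (1.0 - np.exp(-t[pre] / tau_c))

    ph2 = t >= p.td_p
    if np.any(ph2):
        out[ph2] = p.vo2_base + p.ap * (1.0 - np.exp(-(t[ph2] - p.td_p) / p.tau_p))

    sc = t >= p.sc_onset
    if p.a_s > 0 and np.any(sc):
        out[sc] = out[sc] + p.a_s * (1.0 - np.exp(-(t[sc] - p.sc_onset) / p.sc_tau))
    return float(out[0]) if scalar else out


def true_hr_response(t, p: TruthParams):
    """Noiseless HR (bpm): delay-free mono-exponential rise from onset."""
    scalar = np.isscalar(t) or getattr(t, "ndim", 0) == 0
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.full(t.shape, p.hr_base)
    ex = t >= 0
    out[ex] = p.hr_base + p.hr_amp * (1.0 - np.exp(-t[ex] / p.hr_tau))
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# breath-time sampling
# ---------------------------------------------------------------------------

def _breath_times(rng, n: NoiseParams, t_start, t_end, vo2_fraction):
    """Sequential breath times on [t_start, t_end].

    ``vo2_fraction(t)`` maps time to the 0–1 position of true VO2 between
    baseline and peak; the inter-breath interval shrinks linearly from
    ``breath_interval_base`` to ``breath_interval_min`` with that fraction,
    with 8% multiplicative jitter (floored at 40% of the minimum interval).
    """
    times = []
    t = float(t_start)
    while t <= t_end:
        times.append(t)
        frac = float(np.clip(vo2_fraction(t), 0.0, 1.0))
        base = n.breath_interval_base + (n.breath_interval_min - n.breath_interval_base) * frac
        jitter = 1.0 + 0.08 * rng.standard_normal()
        dt = max(base * jitter, 0.4 * n.breath_interval_min)
        t += dt
    return np.asarray(times)


def _inject_artifacts(rng, n: NoiseParams, t, vo2):
    """Multiply isolated breaths by ``artifact_scale`` at the Poisson rate.

    Returns the modified VO2 array and the boolean injection mask.
    """
    mask = np.zeros(t.size, dtype=bool)
    if n.artifact_rate <= 0:
        return vo2, mask
    vo2 = vo2.copy()
    dts = np.diff(t, prepend=t[0] - np.median(np.diff(t)))
    hit = rng.random(t.size) < n.artifact_rate * dts / 60.0
    prev_hit = False
    for i in range(t.size):
        if hit[i] and not prev_hit:
            vo2[i] *= n.artifact_scale
            mask[i] = True
            prev_hit = True
        else:
            prev_hit = False
    return vo2, mask


# ---------------------------------------------------------------------------
# protocol simulators
# ---------------------------------------------------------------------------

def simulate_transition(
    p: TruthParams,
    n: NoiseParams,
    meta: SessionMeta,
    exercise_duration: float = 480.0,
    return_truth: bool = False,
):
    """Simulate one square-wave constant-load session breath by breath.

    The recording spans the full baseline (``meta.transition_onset`` seconds
    at 20 W) plus ``exercise_duration`` seconds of loaded cycling. Identical
    arguments and seed give bit-identical output. With ``return_truth`` the
    series comes with a dict of the noiseless channel values and the
    artifact-injection mask, for recovery studies.
    """
    if meta.protocol != "square_wave":
        raise ValidationError("simulate_transition needs a square_wave protocol")
    rng = np.random.default_rng(n.seed)
    onset = meta.transition_onset
    peak = p.vo2_base + p.ap + p.a_s

    def frac(t_abs):
        v = true_response(t_abs - onset, p)
        return (v - p.vo2_base) / max(peak - p.vo2_base, 1e-9)

    t = _breath_times(rng, n, 0.0, onset + exercise_duration, frac)
    t_rel = t - onset

    vo2 = true_response(t_rel, p) + n.vo2_sd * rng.standard_normal(t.size)
    hr = true_hr_response(t_rel, p) + n.hr_sd * rng.standard_normal(t.size)
    # companion channels: near-steady RER below 1, VE tracking VCO2
    vco2 = 0.88 * true_response(t_rel, p) + 0.9 * n.vo2_sd * rng.standard_normal(t.size)
    ve = 26.0 * 0.88 * true_response(t_rel, p) + 1.5 * rng.standard_normal(t.size)

    vo2, artifact_mask = _inject_artifacts(rng, n, t, vo2)
    series = BreathSeries(
        meta=meta,
        t=t,
        vo2=np.clip(vo2, 0.0, None),
        vco2=np.clip(vco2, 0.0, None),
        ve=np.clip(ve, 0.0, None),
        hr=np.clip(hr, 1.0, 249.0),
    )
    if return_truth:
        truth = {
            "vo2_true": true_response(t_rel, p),
            "hr_true": true_hr_response(t_rel, p),
            "artifact_mask": artifact_mask,
        }
        return series, truth
    return series


def ramp_workload(t, meta: SessionMeta):
    """Instantaneous work rate (W) at time ``t`` relative to ramp onset."""
    t = np.asarray(t, dtype=float)
    rate = meta.ramp_rate if meta.ramp_rate is not None else 30.0
    w = meta.baseline_load + np.where(t >= 0, rate / 60.0 * t, 0.0)
    return w if w.shape else float(w)


def _ramp_vo2(w, rt: RampTruth):
    return np.minimum(rt.vo2_rest + rt.gain * np.asarray(w, dtype=float), rt.vo2max_cap)


def _ramp_vco2(vo2, rt: RampTruth):
    vo2 = np.asarray(vo2, dtype=float)
    s1 = rt.vco2_slope_below
    s2 = s1 * rt.slope_ratio_above_get
    vco2_rest = 0.85 * rt.vo2_rest
    below = vco2_rest + s1 * (vo2 - rt.vo2_rest)
    above = vco2_rest + s1 * (rt.get_vo2 - rt.vo2_rest) + s2 * (vo2 - rt.get_vo2)
    return np.where(vo2 <= rt.get_vo2, below, above)


def simulate_ramp(
    rt: RampTruth,
    n: NoiseParams,
    meta: SessionMeta,
    plateau_duration: float = 90.0,
) -> BreathSeries:
    """Simulate an incremental ramp test breath by breath.

    Four minutes of 20 W stabilisation precede the ramp
    (``meta.ramp_rate`` W·min⁻¹, default 30 = 1 W every 2 s). The test ends
    when true VO2 reaches ``vo2max_cap``; with ``plateau`` set it continues
    ``plateau_duration`` further seconds at the capped VO2 while the work
    rate keeps rising, emulating a terminal plateau.
    """
    if meta.protocol != "ramp":
        raise ValidationError("simulate_ramp needs a ramp protocol")
    rng = np.random.default_rng(n.seed)
    onset = meta.transition_onset
    rate = meta.ramp_rate if meta.ramp_rate is not None else 30.0

    w_cap = (rt.vo2max_cap - rt.vo2_rest) / rt.gain
    t_cap = (w_cap - meta.baseline_load) * 60.0 / rate
    t_end = onset + t_cap + (plateau_duration if rt.plateau else 0.0)

    vo2_at_base = float(_ramp_vo2(meta.baseline_load, rt))

    def frac(t_abs):
        w = ramp_workload(t_abs - onset, meta)
        v = _ramp_vo2(w, rt)
        return (v - vo2_at_base) / max(rt.vo2max_cap - vo2_at_base, 1e-9)

    t = _breath_times(rng, n, 0.0, t_end, frac)
    t_rel = t - onset
    w = ramp_workload(t_rel, meta)
    vo2_true = _ramp_vo2(w, rt)
    vco2_true = _ramp_vco2(vo2_true, rt)
    hr_true = np.minimum(rt.hr_rest + rt.hr_gain * w, rt.hr_max)

    vo2 = vo2_true + n.vo2_sd * rng.standard_normal(t.size)
    vco2 = vco2_true + 0.9 * n.vo2_sd * rng.standard_normal(t.size)
    ve = 26.0 * vco2_true + 1.5 * rng.standard_normal(t.size)
    hr = hr_true + n.hr_sd * rng.standard_normal(t.size)
    vo2, _ = _inject_artifacts(rng, n, t, vo2)

    return BreathSeries(
        meta=meta,
        t=t,
        vo2=np.clip(vo2, 0.0, None),
        vco2=np.clip(vco2, 0.0, None),
        ve=np.clip(ve, 0.0, None),
        hr=np.clip(hr, 1.0, 249.0),
    )


def write_truth_json(path: str | Path, truth, noise: NoiseParams) -> Path:
    """Persist generator ground truth next to a simulated recording."""
    payload = {"truth": asdict(truth), "noise": asdict(noise)}
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return path


def with_seed(n: NoiseParams, seed: int) -> NoiseParams:
    """Convenience: a copy of ``n`` with a different seed."""
    return replace(n, seed=int(seed))
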