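"""Breath-by-breath cleaning chain.

The stages, in the order they are applied to each recording:

1. optional manual exclusion of flagged breaths (sighs/coughs);
2. rolling 3-SD outlier rejection against the local mean;
3. linear interpolation onto a 1-s grid aligned to exercise onset;
4. ensemble averaging of repeated same-condition trials;
5. reduction to non-overlapping 5-s stationary means;
6. exclusion of the cardiodynamic phase (first 20 s of exercise).

Time inside :class:`UniformSeries` is always expressed relative to the
exercise onset (t = 0 at the work-rate step).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .breath_io import BreathSeries, ValidationError

__all__ = [
    "UniformSeries",
    "CleanReport",
    "remove_artifacts",
    "interpolate_1s",
    "ensemble_average",
    "bin_5s",
    "exclude_cardiodynamic",
    "baseline_mean",
    "clean_transition",
    "CARDIO_PHASE_S",
]

#: duration of the cardiodynamic phase excluded from all fitting, s
CARDIO_PHASE_S = 20.0

#: window (s before onset) over which channel baselines are averaged
BASELINE_WINDOW_S = 60.0


@dataclass
class UniformSeries:
    """One evenly sampled channel aligned to exercise onset.

    ``t`` holds sample times (s, onset at 0) on a ``dt``-spaced grid; a gap is
    permitted only where samples were deliberately excluded (cardiodynamic
    phase), so every time is congruent to the grid.
    """

    t: np.ndarray
    values: np.ndarray
    dt: float
    channel: str

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.size != self.values.size:
            raise ValidationError("time and value arrays differ in length")
        if self.t.size == 0:
            raise ValidationError("empty uniform series")
        if self.t.size > 1:
            d = np.diff(self.t)
            if np.any(d <= 0):
                raise ValidationError("uniform-series times must increase")
            steps = d / self.dt
            if not np.allclose(steps, np.round(steps), atol=1e-6):
                raise ValidationError("samples are not on the dt grid")

    @property
    def t0(self) -> float:
        return float(self.t[0])

    @property
    def span(self) -> tuple[float, float]:
        return float(self.t[0]), float(self.t[-1])

    def window(self, lo: float, hi: float) -> "UniformSeries":
        """Sub-series with lo <= t <= hi (inclusive both ends)."""
        m = (self.t >= lo) & (self.t <= hi)
        if not np.any(m):
            raise ValidationError(f"no samples in window [{lo}, {hi}]")
        return UniformSeries(self.t[m], self.values[m], self.dt, self.channel)


@dataclass
class CleanReport:
    """Bookkeeping of the artifact-rejection stage."""

    n_input: int
    n_removed_manual: int
    n_removed_3sd: int
    removed_times: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_removed_manual + self.n_removed_3sd != len(self.removed_times):
            raise ValidationError("removal counts inconsistent with removed_times")


# ---------------------------------------------------------------------------
# stage 1–2: artifact rejection
# ---------------------------------------------------------------------------

def _local_window_bounds(i: int, n: int, window: int) -> tuple[int, int]:
    """Index range [lo, hi) of the ``window`` breaths centred on ``i``.

    Near the series edges the window is shifted (not shrunk) so that it stays
    fully inside the series.
    """
    half = window // 2
    lo = i - half
    hi = lo + window
    if lo < 0:
        lo, hi = 0, window
    elif hi > n:
        lo, hi = n - window, n
    return lo, hi


def remove_artifacts(
    series: BreathSeries,
    window: int = 15,
    exclude_times: tuple[float, ...] = (),
) -> tuple[BreathSeries, CleanReport]:
    """Reject aberrant breaths from a recording.

    Breaths listed in ``exclude_times`` (matched to the nearest breath within
    0.5 s) are removed first — the manual sigh/cough step. Then, in a single
    pass over the remaining breaths, a breath is removed when its VO2 deviates
    from the local mean by more than three local standard deviations, where
    mean and SD are taken over the ``window`` breaths centred on it, the
    candidate itself excluded. All channels of a removed breath go with it.
    """
    if window < 5 or window % 2 == 0:
        raise ValidationError("window must be odd and >= 5")

    n0 = len(series)
    keep = np.ones(n0, dtype=bool)
    removed_manual: list[float] = []
    for tx in exclude_times:
        j = int(np.argmin(np.abs(series.t - tx)))
        if abs(series.t[j] - tx) <= 0.5 and keep[j]:
            keep[j] = False
            removed_manual.append(float(series.t[j]))
    work = series.subset(keep) if removed_manual else series

    n = len(work)
    if n < window:
        raise ValidationError(f"series of {n} breaths is shorter than the {window}-breath window")

    vo2 = work.vo2
    flag = np.zeros(n, dtype=bool)
    for i in range(n):
        lo, hi = _local_window_bounds(i, n, window)
        neigh = np.concatenate((vo2[lo:i], vo2[i + 1:hi]))
        m = neigh.mean()
        s = neigh.std(ddof=1)
        # strict inequality: a constant series (SD = 0, deviation 0) keeps all
        flag[i] = abs(vo2[i] - m) > 3.0 * s
    removed_3sd = [float(t) for t in work.t[flag]]
    cleaned = work.subset(~flag)

    report = CleanReport(
        n_input=n0,
        n_removed_manual=len(removed_manual),
        n_removed_3sd=len(removed_3sd),
        removed_times=sorted(removed_manual + removed_3sd),
    )
    return cleaned, report


# ---------------------------------------------------------------------------
# stage 3: interpolation and alignment
# ---------------------------------------------------------------------------

def interpolate_1s(series: BreathSeries, channel: str = "vo2") -> UniformSeries:
    """Linearly interpolate one channel onto the 1-s grid.

    The grid covers the integer seconds inside the recording span — no
    extrapolation — and is re-expressed relative to ``transition_onset`` so
    that t = 0 is the start of loaded exercise.
    """
    vals = series.channel(channel)
    finite = np.isfinite(vals)
    if finite.sum() < 2:
        raise ValidationError(f"channel {channel!r} has fewer than 2 finite breaths")
    t_rel = series.t[finite] - series.meta.transition_onset
    v = vals[finite]
    lo = int(np.ceil(t_rel[0]))
    hi = int(np.floor(t_rel[-1]))
    if hi < lo:
        raise ValidationError("recording spans no full second")
    grid = np.arange(lo, hi + 1, dtype=float)
    return UniformSeries(grid, np.interp(grid, t_rel, v), dt=1.0, channel=channel)


# ---------------------------------------------------------------------------
# stage 4: ensemble averaging of repeated trials
# ---------------------------------------------------------------------------

def ensemble_average(a: UniformSeries, b: UniformSeries) -> UniformSeries:
    """Pointwise mean of two aligned same-channel series on the overlap."""
    if a.channel != b.channel:
        raise ValidationError(f"channel mismatch: {a.channel!r} vs {b.channel!r}")
    if a.dt != b.dt:
        raise ValidationError("dt mismatch")
    common, ia, ib = np.intersect1d(a.t, b.t, return_indices=True)
    if common.size == 0:
        raise ValidationError("series spans are disjoint")
    return UniformSeries(common, 0.5 * (a.values[ia] + b.values[ib]), a.dt, a.channel)


def ensemble_average_many(series: list[UniformSeries]) -> UniformSeries:
    out = series[0]
    for s in series[1:]:
        out = ensemble_average(out, s)
    return out


# ---------------------------------------------------------------------------
# stage 5: 5-s stationary means
# ---------------------------------------------------------------------------

def bin_5s(series: UniformSeries) -> UniformSeries:
    """Reduce a 1-s series to non-overlapping 5-s means.

    Bins partition the axis anchored at the exercise onset: forward bins
    [0, 5), [5, 10), … and backward bins [-5, 0), [-10, -5), …, so no bin
    straddles t = 0. A bin is emitted only when all five 1-s samples are
    present; its timestamp is the central sample's time.
    """
    if series.dt != 1.0:
        raise ValidationError("bin_5s expects a 1-s series")
    if series.t[-1] - series.t[0] < 4:
        raise ValidationError("series spans less than 5 s")
    index = {float(t): i for i, t in enumerate(series.t)}
    t_lo, t_hi = series.span

    starts = []
    s = 0.0
    while s + 4 <= t_hi:
        starts.append(s)
        s += 5.0
    s = -5.0
    while s >= t_lo:
        starts.append(s)
        s -= 5.0

    times, means = [], []
    for s in sorted(starts):
        idx = [index.get(s + k) for k in range(5)]
        if any(i is None for i in idx):
            continue
        times.append(s + 2.0)
        means.append(series.values[np.asarray(idx)].mean())
    if not times:
        raise ValidationError("no complete 5-s bin in series")
    return UniformSeries(np.asarray(times), np.asarray(means), dt=5.0, channel=series.channel)


# ---------------------------------------------------------------------------
# stage 6: cardiodynamic exclusion
# ---------------------------------------------------------------------------

def exclude_cardiodynamic(series: UniformSeries) -> UniformSeries:
    """Drop samples in [0, 20) s; baseline (t < 0) is retained."""
    m = ~((series.t >= 0) & (series.t < CARDIO_PHASE_S))
    if not np.any(m):
        raise ValidationError("nothing left after cardiodynamic exclusion")
    if not np.any(series.t[m] >= CARDIO_PHASE_S):
        warnings.warn("empty exercise segment after cardiodynamic exclusion", stacklevel=2)
    return UniformSeries(series.t[m], series.values[m], series.dt, series.channel)


# ---------------------------------------------------------------------------
# helpers / orchestration
# ---------------------------------------------------------------------------

def baseline_mean(series: UniformSeries, window_s: float = BASELINE_WINDOW_S) -> float:
    """Mean over the last ``window_s`` seconds before onset, t in [-window, 0)."""
    m = (series.t >= -window_s) & (series.t < 0)
    if not np.any(m):
        raise ValidationError("no baseline samples in the requested window")
    return float(series.values[m].mean())


def clean_transition(
    trials: list[BreathSeries],
    channels: tuple[str, ...] = ("vo2", "hr"),
    window: int = 15,
    exclude_times: tuple[tuple[float, ...], ...] | None = None,
) -> dict:
    """Run the full cleaning chain on one condition's repeated trials.

    Returns a dict with, per channel, the ensemble-averaged 1-s series
    (``<ch>_1s``), the cardio-excluded 5-s series (``<ch>_5s``) and the
    last-minute baseline (``<ch>_baseline``), plus the per-trial
    :class:`CleanReport` list under ``"reports"``.
    """
    if exclude_times is None:
        exclude_times = tuple(() for _ in trials)
    cleaned, reports = [], []
    for trial, excl in zip(trials, exclude_times):
        c, rep = remove_artifacts(trial, window=window, exclude_times=excl)
        cleaned.append(c)
        reports.append(rep)

    out: dict = {"reports": reports}
    for ch in channels:
        one_s = ensemble_average_many([interpolate_1s(c, ch) for c in cleaned])
        out[f"{ch}_1s"] = one_s
        out[f"{ch}_baseline"] = baseline_mean(one_s)
        out[f"{ch}_5s"] = exclude_cardiodynamic(bin_5s(one_s))
    return out
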