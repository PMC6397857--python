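"""Phase-II fitting, slow-component detection, MRT and O2-pulse derivation."""

import dataclasses

import numpy as np
import pytest

from vo2kinetics import SessionMeta, simulate_transition
from vo2kinetics.breath_io import ValidationError
from vo2kinetics.kinetics import (
    analyze_condition,
    compute_o2_pulse,
    detect_slow_component,
    fit_mrt,
    fit_phase2,
)
from vo2kinetics.preprocess import UniformSeries, clean_transition
from vo2kinetics.synthetic_data import DEFAULT_NOISE, DEFAULT_TRUTH


def exp_series(t, base, ap, tau, td, channel="vo2"):
    t = np.asarray(t, dtype=float)
    v = np.where(t >= td, base + ap * (1.0 - np.exp(-np.clip(t - td, 0, None) / tau)), base)
    dt = float(t[1] - t[0])
    return UniformSeries(t, v, dt, channel)


# -- phase II ---------------------------------------------------------------

def test_phase2_noiseless_recovery_to_machine_precision():
    s = exp_series(np.arange(22.0, 241.0, 5.0), 1.1, 2.0, 48.0, 5.0)
    f = fit_phase2(s, baseline=1.1, window=(20.0, 240.0))
    assert f.ap == pytest.approx(2.0, rel=1e-6)
    assert f.tau_p == pytest.approx(48.0, rel=1e-6)
    assert f.td_p == pytest.approx(5.0, rel=1e-4)
    assert f.r2 == pytest.approx(1.0)
    assert f.ci_tau[0] <= f.tau_p <= f.ci_tau[1]


def test_phase2_constant_series_flags_unidentifiable_tau():
    s = UniformSeries(np.arange(22.0, 241.0, 5.0), np.full(44, 1.1), 5.0, "vo2")
    f = fit_phase2(s, baseline=1.1, window=(20.0, 240.0))
    assert not f.identifiable
    assert f.ap < 0.05


def test_phase2_window_preconditions():
    s = exp_series(np.arange(22.0, 241.0, 5.0), 1.1, 2.0, 48.0, 5.0)
    with pytest.raises(ValidationError):
        fit_phase2(s, 1.1, (10.0, 240.0))  # inside cardiodynamic phase
    with pytest.raises(ValidationError):
        fit_phase2(s, 1.1, (20.0, 50.0))  # too few samples


def test_phase2_monte_carlo_calibration(sw_meta):
    """n-of-1 recovery at default noise: unbiased τ, calibrated 95% CI."""
    errs, cover = [], 0
    n_rep = 120
    for seed in range(1, n_rep + 1):
        s = simulate_transition(
            DEFAULT_TRUTH, dataclasses.replace(DEFAULT_NOISE, seed=seed), sw_meta
        )
        b = clean_transition([s], channels=("vo2",))
        f = fit_phase2(b["vo2_5s"], b["vo2_baseline"], (20.0, DEFAULT_TRUTH.sc_onset))
        errs.append(f.tau_p - DEFAULT_TRUTH.tau_p)
        cover += f.ci_tau[0] <= DEFAULT_TRUTH.tau_p <= f.ci_tau[1]
    assert abs(np.mean(errs)) <= 3.0
    assert 0.90 <= cover / n_rep <= 0.99


def test_ci_width_shrinks_with_longer_uncontaminated_window(sw_meta):
    truth = dataclasses.replace(DEFAULT_TRUTH, a_s=0.0)
    s = simulate_transition(truth, dataclasses.replace(DEFAULT_NOISE, seed=3), sw_meta)
    b = clean_transition([s], channels=("vo2",))
    widths = [
        fit_phase2(b["vo2_5s"], b["vo2_baseline"], (20.0, t_end)).ci_width
        for t_end in (90.0, 120.0, 240.0, 480.0)
    ]
    # residual-variance estimation adds jitter step to step, but quadrupling
    # the uncontaminated window must narrow the interval
    assert widths[-1] < widths[0] and widths[-1] < widths[1]
    assert widths[2] < widths[0]


# -- slow component ---------------------------------------------------------

def test_pure_monoexponential_reports_no_slow_component(sw_meta, noiseless_noise):
    truth = dataclasses.replace(DEFAULT_TRUTH, a_s=0.0)
    s = simulate_transition(truth, noiseless_noise, sw_meta)
    b = clean_transition([s], channels=("vo2",))
    slow, _ = detect_slow_component(b["vo2_5s"], b["vo2_baseline"])
    assert not slow.detected
    assert slow.a_s == 0.0


def test_noiseless_slow_component_onset_and_amplitude(sw_meta, noiseless_noise):
    truth = dataclasses.replace(DEFAULT_TRUTH, a_s=0.25, sc_onset=120.0)
    s = simulate_transition(truth, noiseless_noise, sw_meta)
    b = clean_transition([s], channels=("vo2",))
    slow, fit = detect_slow_component(b["vo2_5s"], b["vo2_baseline"])
    assert slow.detected
    assert abs(slow.onset - 120.0) <= 15.0
    assert slow.a_s == pytest.approx(0.25, abs=0.03)
    assert fit.tau_p == pytest.approx(truth.tau_p, abs=0.5)


def test_slow_component_requires_240s_span():
    s = exp_series(np.arange(22.0, 200.0, 5.0), 1.1, 2.0, 48.0, 5.0)
    with pytest.raises(ValidationError):
        detect_slow_component(s, 1.1)


def test_criteria_trace_records_all_candidates(sw_meta, noiseless_noise):
    s = simulate_transition(DEFAULT_TRUTH, noiseless_noise, sw_meta)
    b = clean_transition([s], channels=("vo2",))
    slow, _ = detect_slow_component(b["vo2_5s"], b["vo2_baseline"])
    t_ends = [r["t_end"] for r in slow.criteria_trace]
    assert t_ends == sorted(t_ends)
    assert t_ends[0] >= 60.0 and t_ends[-1] <= 420.0
    assert all({"ci_width", "Ap", "tau", "TD", "r2"} <= set(r) for r in slow.criteria_trace)


def test_slow_component_amplitude_identity(sw_meta):
    """As = vo2_end - (base + Ap) holds bit-exactly whenever detected."""
    for seed in (2, 5, 9):
        s = simulate_transition(DEFAULT_TRUTH, dataclasses.replace(DEFAULT_NOISE, seed=seed), sw_meta)
        b = clean_transition([s], channels=("vo2",))
        slow, fit = detect_slow_component(b["vo2_5s"], b["vo2_baseline"])
        if slow.detected:
            assert slow.vo2_end - fit.vo2_base - fit.ap - slow.a_s == 0.0


# -- mean response time -----------------------------------------------------

def test_mrt_equals_tau_for_delay_free_exponential():
    s = exp_series(np.arange(1.0, 481.0), 1.0, 2.3, 60.0, 0.0)
    f = fit_mrt(s, end_time=480.0)
    assert f.mrt == pytest.approx(60.0, rel=1e-6)
    assert f.base == pytest.approx(1.0, rel=1e-6)


def test_mrt_with_delay_matches_grid_search_oracle():
    """Delay-free fit to delayed data: MRT ≈ TD + τ, equal to a brute-force
    profile-likelihood oracle over τ."""
    t = np.arange(1.0, 481.0)
    s = exp_series(t, 1.0, 2.0, 50.0, 10.0)

    best_tau, best_sse = None, np.inf
    for tau in np.arange(30.0, 90.0, 0.05):
        g = 1.0 - np.exp(-t / tau)
        design = np.column_stack((np.ones_like(t), g))
        coef, *_ = np.linalg.lstsq(design, s.values, rcond=None)
        resid = design @ coef - s.values
        sse = float(resid @ resid)
        if sse < best_sse:
            best_tau, best_sse = tau, sse
    f = fit_mrt(s, end_time=480.0)
    assert f.mrt == pytest.approx(best_tau, abs=0.1)
    # free-baseline absorption pulls MRT below TD + tau; it stays between
    # the phase time constant and the delayed sum
    assert 50.0 <= f.mrt <= 60.0


def test_mrt_constant_series_flagged():
    s = UniformSeries(np.arange(1.0, 200.0), np.full(199, 1.2), 1.0, "hr")
    f = fit_mrt(s, end_time=180.0)
    assert f.amplitude == pytest.approx(0.0, abs=1e-6)
    assert not f.identifiable


# -- O2 pulse ---------------------------------------------------------------

def test_o2_pulse_unit_arithmetic_and_scale_invariance():
    t = np.arange(0.0, 10.0)
    vo2 = UniformSeries(t, np.full(10, 3.0), 1.0, "vo2")
    hr = UniformSeries(t, np.full(10, 150.0), 1.0, "hr")
    np.testing.assert_allclose(compute_o2_pulse(vo2, hr).values, 20.0)
    vo2x2 = UniformSeries(t, vo2.values * 2, 1.0, "vo2")
    hrx2 = UniformSeries(t, hr.values * 2, 1.0, "hr")
    np.testing.assert_allclose(compute_o2_pulse(vo2x2, hrx2).values, 20.0)


def test_o2_pulse_matches_division_oracle_and_validates_hr():
    rng = np.random.default_rng(13)
    t = np.arange(0.0, 50.0)
    vo2 = UniformSeries(t, rng.uniform(1, 4, 50), 1.0, "vo2")
    hr = UniformSeries(t, rng.uniform(60, 190, 50), 1.0, "hr")
    np.testing.assert_allclose(
        compute_o2_pulse(vo2, hr).values, 1000.0 * vo2.values / hr.values, rtol=1e-15
    )
    bad = UniformSeries(t, np.concatenate([[0.0], hr.values[1:]]), 1.0, "hr")
    with pytest.raises(ValidationError, match="t=0"):
        compute_o2_pulse(vo2, bad)


# -- orchestration ----------------------------------------------------------

def test_two_identical_trials_equal_single_trial_analysis(sw_meta):
    s = simulate_transition(DEFAULT_TRUTH, dataclasses.replace(DEFAULT_NOISE, seed=4), sw_meta)
    one = clean_transition([s])
    two = clean_transition([s, s])
    r1 = analyze_condition(one["vo2_5s"], one["hr_5s"], one["vo2_baseline"])
    r2 = analyze_condition(two["vo2_5s"], two["hr_5s"], two["vo2_baseline"])
    assert r1.variables() == r2.variables()


def test_analyze_condition_noiseless_matches_truth(noiseless_bundle):
    res = analyze_condition(
        noiseless_bundle["vo2_5s"], noiseless_bundle["hr_5s"], noiseless_bundle["vo2_baseline"]
    )
    v = res.variables()
    assert v["vo2_base"] == pytest.approx(DEFAULT_TRUTH.vo2_base, abs=1e-3)
    assert v["tau_p"] == pytest.approx(DEFAULT_TRUTH.tau_p, abs=0.5)
    assert v["Ap"] == pytest.approx(DEFAULT_TRUTH.ap, abs=0.01)
    assert v["TD_p"] == pytest.approx(DEFAULT_TRUTH.td_p, abs=0.5)
    assert v["As"] == pytest.approx(DEFAULT_TRUTH.a_s, abs=0.01)
    assert v["HR_base"] == pytest.approx(DEFAULT_TRUTH.hr_base, abs=0.5)
    assert v["MRT_180s_hr"] == pytest.approx(DEFAULT_TRUTH.hr_tau, rel=0.02)
    # end-exercise VO2 equals base + Ap + (almost saturated) slow component
    assert v["A_t"] == pytest.approx(
        DEFAULT_TRUTH.vo2_base + DEFAULT_TRUTH.ap + DEFAULT_TRUTH.a_s, abs=0.01
    )
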