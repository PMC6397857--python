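# Methods

## Scope

`vo2kinetics` analyses pulmonary oxygen-uptake (VO2) on-kinetics from
breath-by-breath gas-exchange recordings of constant-load (square-wave)
cycling transitions, and derives the incremental-ramp indexes (VO2max, gas
exchange threshold, Δ50% intensity) used to prescribe those transitions. A
synthetic breath-by-breath generator with known ground truth stands in for
raw metabolic-cart exports, so every stage of the pipeline can be tested
against the parameters that generated its input.

## Signal model

During a square-wave transition from 20 W baseline to a heavy constant load,
VO2 is modelled in three phases:

* a **cardiodynamic phase** in the first seconds after onset, driven by the
  abrupt rise in pulmonary blood flow, excluded from all fitting (first
  20 s);
* **phase II**, the fundamental mono-exponential rise,

      VO2(t) = VO2_base + Ap · (1 − e^−(t−TDp)/τp),   t ≥ TDp,

  with the baseline *fixed* at the measured mean over the last minute of the
  20 W period and (Ap, τp, TDp) free. We read "constrained in the baseline"
  as *fixed* rather than merely bounded: it removes one degree of freedom
  that otherwise trades against τp, and the last-minute 20-W mean is
  measured with ~0.013 L·min⁻¹ standard error, whose effect on τ̂p is
  negligible (it is absorbed by Ap and TDp; verified numerically);
* a **slow component**, an additional delayed rise during heavy exercise,
  quantified as an end-exercise excess

      As = VO2_end − (VO2_base + Ap),

  with VO2_end the mean over the last 15 s of exercise. As is reported as 0
  when the excess does not exceed 0.05 L·min⁻¹ (the detection floor that
  replaces visual inspection of residual plots).

Overall ("effective") kinetics are summarised by the **mean response time**
(MRT): the time constant of a delay-free mono-exponential
`y(t) = base + A·(1 − e^−t/MRT)` fitted from exercise onset to 480 s for
VO2, and to 180 s for heart rate and O2 pulse (HR and O2-pulse responses are
adequately mono-exponential only over the early transient). O2 pulse is
VO2/HR in mL·beat⁻¹, formed pointwise on the aligned 1-s grids. All MRT
parameters, including the baseline, are free.

## Cleaning chain

1. optional manual exclusion of flagged breaths (sighs/coughs), given as
   explicit times;
2. **3-SD rejection**: a breath is removed when its VO2 deviates from the
   local mean by more than three local standard deviations, computed over
   the 15 breaths centred on it (shifted, not shrunk, at the record edges),
   the candidate itself excluded; one pass, no iteration;
3. linear interpolation of each channel onto a 1-s grid, re-expressed
   relative to exercise onset (t = 0 at the step);
4. pointwise ensemble averaging of the two same-condition trials over their
   common grid;
5. reduction to 5-s stationary means, bins anchored at t = 0 forward and
   backward so none straddles the onset; bin timestamp = central sample;
6. removal of the cardiodynamic samples (0 ≤ t < 20 s).

Model fits use the 5-s series; channel baselines use the 1-s series over
t ∈ [−60, 0).

The window width (15 breaths) is a design choice: wide enough for a stable
SD estimate, short relative to τp so the local mean tracks the transient.
Single-pass rejection has a measurable ceiling: at the default artifact rate
(0.5 min⁻¹) about a quarter of spikes have another spike among their window
neighbours, which inflates the local SD and can mask them, and the local SD
is also inflated by the on-transient trend. Measured on the default
generator, sensitivity is ≈0.91 with ≈0.8% false positives; iterative or
robust (median/MAD) variants would do better but are deliberately out of
scope.

## Slow-component onset detection

Phase II must be fitted "from the end of the cardiodynamic phase to the
beginning of the slow component", so the fit-window end is itself estimated.
Candidate windows [20, t_end] are fitted for t_end on a 5-s grid in
[60, 420] s (skipping candidates with fewer than 10 binned samples). Three
selection rules apply in order:

1. **Residual-forecast breakpoint** (operative rule). Each candidate fit
   predicts the 30 s beyond its window; the mean forecast residual,
   standardized by the running-median fit rmse, jumps once the slow
   component enters the horizon. The first t_end ≥ 90 s with two
   consecutive z > 2.5 (and a physical excess > 0.01 L·min⁻¹, so that
   noise-free data cannot trigger on rounding error) brackets the onset
   inside (t_end, t_end + 30]; the fit window ends 10 s after the crossing.
2. **Narrowest-CI local minimum.** The 95% CI of τp narrows ~1/√n while the
   window is uncontaminated and inflates when contaminated; the first
   sustained local minimum (narrower than the previous and the next four
   candidates) marks the onset. This classic criterion is kept as the
   fallback because at realistic noise (slow component ≈0.22 L·min⁻¹
   against ≈0.05 L·min⁻¹ per-bin noise) the CI-width signature is often
   statistically invisible while the forecast-residual signature is not:
   the mono-exponential absorbs the slow component by inflating Ap, leaving
   the CI shrinking monotonically to the longest window (+17 s τ bias when
   the global minimum is used naively).
3. **Global narrowest CI**, ties to the latest window — the pure
   mono-exponential case, where using the whole response is optimal.

All per-candidate diagnostics (CI width, forecast z, Ap, τ, TD, r²) are
retained in `criteria_trace`.

With two ensemble-averaged trials per condition the end-to-end τ̂p error is
≈4 s in median at default noise. This is close to the information limit: the
Cramér–Rao bound for (Ap, τ, TD) with fixed baseline on the uncontaminated
window alone is se(τ) ≈ 5.3 s for the two-trial average (≈7.5 s for a single
trial), so single-transition τ estimates are intrinsically imprecise — the
reason the protocol averages repeated trials. About 15–20% of simulated
subjects have a slow component that no deterministic rule can separate from
noise; in those cases the window extends late, As reports 0 and τ̂p is
biased high. The CI coverage of the τ interval is nominal (≈95%) when the
window is uncontaminated; end-to-end coverage is lower because of exactly
those undetectable-slow-component subjects.

## Fitting machinery

Nonlinear least squares (scipy `least_squares`, TRF, analytic Jacobians)
with multi-start over τ ∈ {20, 40, 60, 90} × TD ∈ {0, 10, 20} and a
data-driven amplitude start; bounds Ap ∈ [0, 5] L·min⁻¹, τ ∈ (0, 200] s,
TD ∈ [0, 35] s; ties in SSE resolve to the smallest τ. During the candidate
scan, each fit warm-starts from its predecessor plus one generic start.
Confidence intervals come from the linearised covariance
`s²(JᵀJ)⁻¹` with a Student-t critical value. Amplitudes below 0.05 (channel
units) flag the time constant as unidentifiable. Equal weights throughout.

## Ramp-test indexes

* **VO2max**: maximum 15-s rolling mean of the 1-s VO2 series over the ramp.
* **Plateau**: some 60-s window during the ramp (skipping the first 30 s,
  which reflect the on-transient) whose second 30-s half-mean exceeds the
  first by *less than* 0.150 L·min⁻¹. Strictly less: a ramp rising exactly
  at the criterion rate (the standard 10 mL·min⁻¹·W⁻¹ gain at 30 W·min⁻¹ is
  precisely that) is not a plateau.
* **GET (V-slope)**: continuous two-segment regression of VCO2 on VO2
  (design `[1, VO2, (VO2 − c)₊]`), breakpoint `c` scanned over observed VO2
  values in the central 80% of the range with ≥3 points on each side,
  minimum SSE subject to upper slope > lower slope. No regional
  preselection or hyperventilation-region exclusion.
* **Δ50%**: GET-VO2 + 0.5·(VO2max − GET-VO2); the corresponding work rate
  inverts an OLS line of VO2 on instantaneous work rate over the ramp
  segment, excluding the first 30 and last 15 s.
* Peak work rate and HRmax are the highest values observed during exercise.
  Report tables round half-up to the printed decimals.

## Synthetic data

The generator emulates the study conditions: square-wave sessions of 3 min
at 20 W plus 8 min at the heavy load, ramp tests of 4 min at 20 W then
+30 W·min⁻¹ to exhaustion. Defaults are the group means of the control
condition (base 1.08, Ap 2.07 L·min⁻¹, τp 50.1 s, TDp 6.1 s, As
0.22 L·min⁻¹; HR 93 → +61 bpm, τ 67 s; ramp gain 0.010 L·min⁻¹·W⁻¹, GET
2.03, VO2max 3.48 L·min⁻¹). Values the source tables do not determine were
fixed once at field-typical levels: slow-component onset 120 s and time
constant 60 s (so the end-exercise excess essentially equals the amplitude,
matching the end-difference definition of As); a 0.15 L·min⁻¹ cardiodynamic
bump over the first 20 s; VCO2 ≈ 0.88·VO2 during transitions and a V-slope
lower slope of 0.90 with ratio 1.4 above GET; ventilation 26 L per L of
VCO2.

Noise: additive Gaussian per breath (VO2 sd 0.10 L·min⁻¹, HR sd 2 bpm);
inter-breath interval shrinking linearly from 3.0 s at baseline VO2 to 1.5 s
at peak with 8% jitter; isolated sigh/cough artifacts ×1.8 at 0.5 min⁻¹
(Poisson). One explicit integer seed per call; identical seeds give
bit-identical recordings. A per-condition parameter delta (default zero)
lets studies inject condition effects.

What the generator does *not* emulate: breath-to-breath autocorrelated
noise, drifting baselines, RER dynamics and ventilatory compensation above
GET, HR variability structure, or any physiology of ischemia-reperfusion
priming. Passing tests therefore demonstrate correctness of the estimators
under the stated noise model, not robustness to every feature of real
metabolic-cart data.

## Simulated studies

A study draws per-subject true parameters from Gaussian priors centred on
the defaults (SDs: base 0.08, Ap 0.5 L·min⁻¹, τp 7 s, TDp 1.75 s, As 0.10
L·min⁻¹, onset 15 s; HR base 13, amplitude 11 bpm, τ 6 s; clipped to
physiological ranges), simulates two trials per condition per subject,
analyses each condition from the ensemble-averaged pair, and compares every
outcome variable between conditions with a two-tailed paired t-test
(analytic p from the t distribution with n−1 df). Type-I error of the whole
chain is nominal under a zero condition effect (checked over 50 replicate
n = 10 studies). Degenerate zero-variance differences are flagged; a log
transformation hook exists but is off by default.

## Problem sizes used in the test suite

Monte-Carlo checks use: 120 single-trial replicates for fitter calibration,
100 two-trial subjects for stochastic recovery, 50 replicate n = 10 studies
for null calibration, 100 profiles for GET recovery, 60 recordings for
cleaning sensitivity, and 20 seeds per brute-force-oracle comparison. These
sizes give sub-unit standard errors on the quantities asserted while keeping
the default `pytest` run around seven minutes.

## Known limitations

* Phase II and slow component are fitted sequentially, not jointly; the
  slow-component time constant itself is not estimated.
* The 3-SD cleaning pass has the sensitivity ceiling described above.
* GET from fully simulated noisy ramps (noise in both VO2 and VCO2) is
  biased low by errors-in-variables in the hinge regression; the V-slope
  oracle tests use noise on VCO2 only, which is the classical setting.
* MRT of a delayed response underestimates TD + τ because the free baseline
  absorbs part of the delay; this is a property of the delay-free model,
  shared with its standard use.
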