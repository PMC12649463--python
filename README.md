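# blinkpath

From eye-landmark geometry to mediation path models: a tested Python
pipeline for studies that relate personality traits to spontaneous
eye-blink rate (SBR) through perceived psychological stress.

Spontaneous blinking is a non-invasive psychophysiological marker tied to
dopaminergic and attentional systems. A common study design records a
participant reading on camera, detects blinks from facial landmarks,
scores personality (BFI-2) and perceived stress (PSS-14) questionnaires,
and asks whether stress *mediates* the trait → blink-rate association.
`blinkpath` implements every computational stage of that chain:

* **`blinkpath.ear`** — eye aspect ratio EAR = (A + B) / (2C) from
  6-point eye landmarks (A, B vertical lid openings, C horizontal
  aperture), averaged over both eyes into a per-frame mEAR series with
  missing-frame masking.
* **`blinkpath.detection`** — blink events as maximal sub-threshold runs,
  durations from run length at the frame rate, a >500 ms exclusion for
  voluntary closures, and blinks-per-minute statistics over complete
  60-s windows.
* **`blinkpath.calibration`** — per-participant threshold calibration by
  bisection against a manual blink count on the first two minutes, with
  a grid-scan fallback and plateau centering for the non-monotone count
  staircase.
* **`blinkpath.psychometrics`** — BFI-2 domain means and PSS-14 totals
  with published keying defaults, Cronbach's α, SPSS-style descriptives
  (G1/G2), and Pearson correlation matrices with two-tailed p values.
* **`blinkpath.mediation`** — the saturated standardized path model
  X → M → Y with direct path, fitted from raw vectors or from a
  correlation triple {r_XM, r_XY, r_MY, n}:

      a  = r_XM
      b  = (r_MY − r_XM·r_XY) / (1 − r_XM²)
      c′ = (r_XY − r_XM·r_MY) / (1 − r_XM²)
      c  = r_XY = c′ + a·b        (exact decomposition)

  with R², t statistics, a percentile bootstrap for the indirect effect
  a·b, and automatic classification into consistent mediation,
  inconsistent ("indirect-only") mediation, or suppression (significant
  direct and indirect effects of opposite sign).
* **`blinkpath.synthetic`** — generators for every input: noisy mEAR
  signals with frame-exact ground-truth blinks, correlated
  trait/stress/blink samples, and keyed Likert item matrices.

## Worked example

```python
from blinkpath import (
    SignalSpec, generate_ear_signal, calibrate_threshold,
    detect_blinks, blink_rate_stats,
    CorrelationInput, fit_mediation,
)

# 1. a five-minute recording with known ground truth
series, truth = generate_ear_signal(SignalSpec(seed=1))

# 2. calibrate the threshold on the first two minutes against a manual count
manual = sum(1 for e in truth if e.valid and e.onset_frame < 120 * series.fps)
cal = calibrate_threshold(series.slice_seconds(0, 120), manual)

# 3. blink rate over the full recording
events = detect_blinks(series, cal.threshold)
summary = blink_rate_stats(events, series)
print(f"threshold={cal.threshold:.3f} converged={cal.converged}")
print(f"mean_bpm={summary.mean_bpm:.1f} sd_bpm={summary.sd_bpm:.2f}")

# 4. mediation from a published correlation triple (n = 86)
m = fit_mediation(CorrelationInput(r_xm=0.35, r_xy=-0.17, r_my=0.27, n=86))
print(f"a={m.a:.2f} b={m.b:.2f} c'={m.c_prime:.2f} "
      f"R2_M={m.r2_m:.0%} R2_Y={m.r2_y:.0%} -> {m.classification}")
```

prints

```
threshold=0.204 converged=True
mean_bpm=16.8 sd_bpm=1.92
a=0.35 b=0.38 c'=-0.30 R2_M=12% R2_Y=15% -> suppression
```

The calibrated threshold reproduces the manual count exactly; the
recording averages ~17 blinks/min. The mediation fit shows the
suppression pattern: a trait with essentially no zero-order association
with blinking (r = −0.17, ns at n = 86) acquires a significant *negative*
direct path (c′ = −0.30) once stress enters, while the indirect path
through stress (a·b = 0.35 × 0.38 ≈ +0.13) is positive — two opposing
mechanisms that cancel in the total effect (−0.30 + 0.13 ≈ −0.17).

A thin CLI mirrors the library: `blinkpath simulate ear`, `blinkpath
simulate traits`, `blinkpath detect`, `blinkpath calibrate`, `blinkpath
score`, `blinkpath mediate` (see `blinkpath --help`).

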