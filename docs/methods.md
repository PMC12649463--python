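# Methods

## Scope and model

`blinkpath` implements the measurement-to-model chain used to relate
Big-Five personality traits to spontaneous eye-blink rate (SBR) through
perceived psychological stress:

1. **EAR signal.** For each video frame, each eye contributes an eye
   aspect ratio EAR = (A + B) / (2C), where A = |p2 − p6| and
   B = |p3 − p5| are the vertical lid openings and C = |p1 − p4| the
   horizontal aperture of the standard 6-point eye contour (68-point
   facial-landmark convention). The detection signal is the per-frame
   mean of the two eyes (mEAR). EAR is a shape ratio: invariant to
   translation, rotation and uniform scaling, non-negative, and near
   zero at full closure.
2. **Blink segmentation.** A blink event is a maximal run of consecutive
   unmasked frames with mEAR below a threshold. Duration is
   run-length / fps. Runs shorter than `min_frames` (default 2, ≈67 ms
   at 30 fps) are discarded as single-frame noise; runs longer than
   `max_duration_ms` (default 500 ms) are kept for audit but flagged
   invalid, filtering voluntary or prolonged closures. The outcome
   measure is the mean and sample SD of valid-blink counts over complete
   non-overlapping 60-s windows (events belong to the window containing
   their onset; a partial trailing window is dropped).
3. **Threshold calibration.** Lid geometry and camera angle shift the
   open-eye EAR baseline between individuals, so the threshold is
   calibrated per participant by bisection on a calibration window
   (conventionally the first two minutes) against a manual blink count:
   automatic count below the manual count raises the lower limit,
   above it lowers the upper limit, halving the bracket until the counts
   agree.
4. **Psychometrics.** BFI-2 domains are item means (12 items each,
   responses 1–5) after reversing reverse-keyed items; the PSS-14 total
   is an item sum (14 items, responses 0–4, positively worded items
   reversed; range 0–56). Keying maps ship as published-instrument
   defaults and can be overridden from JSON. Reliability is Cronbach's
   α with sample variances; descriptives use the adjusted
   Fisher–Pearson skewness (G1) and small-sample-corrected excess
   kurtosis (G2); correlations are Pearson r with two-tailed p from
   t = r√(n−2)/√(1−r²).
5. **Mediation.** The single-mediator triangle X → M → Y with a direct
   path X → Y, fitted on standardized variables. The model is saturated
   (0 df), so maximum-likelihood and OLS point estimates coincide and
   have closed forms in the three pairwise correlations:
   a = r_XM, b = (r_MY − r_XM r_XY)/(1 − r_XM²),
   c′ = (r_XY − r_XM r_MY)/(1 − r_XM²), with the exact decomposition
   c = r_XY = c′ + a·b. R²_M = a²; R²_Y = c′·r_XY + b·r_MY.

## Numerical and inferential choices

* **t statistics.** Finite-sample OLS forms: t_a = a√(n−2)/√(1−a²) on
  n−2 df; for b and c′, t = β / √[(1−R²_Y)/((n−3)(1−r_XM²))] on n−3 df.
  SEM software reports asymptotic critical ratios instead; point
  estimates agree exactly, t values only approximately (within ~0.05 of
  published values on the reference inputs). They are therefore treated
  as approximate diagnostics, not exact reproduction targets.
* **Effect classification** at two-tailed α = 0.05: *suppression* =
  significant indirect pathway (a and b both significant) and a
  significant direct path of opposite sign; *indirect-only*
  (inconsistent mediation) = significant indirect pathway with a
  non-significant direct path; *consistent-mediation* = significant
  indirect pathway and direct path of the same sign; otherwise
  *no-effect*.
* **Bootstrap.** The percentile bootstrap for the indirect effect
  resamples participants, refits the closed forms per replicate
  (vectorized), and reports a seeded percentile interval. Note a known
  structural property: at the *complete* null (a = b = 0) percentile
  intervals for a product of coefficients are conservative — empirical
  coverage of zero is ≈99.8% rather than the nominal 95% (the interval
  excludes zero only when both paths are individually extreme). The
  test suite asserts the interval is never anticonservative at the
  null, excludes zero in a powered case, and is deterministic under a
  seed.
* **Calibration robustness.** The valid-blink count is not monotone in
  the threshold: adjacent runs merge, and very wide runs trip the
  500 ms exclusion, so the count *falls* again at high thresholds. Two
  consequences are handled explicitly. (i) If bisection terminates
  without an exact match, a fine grid scan (default 256 points) of the
  initial interval supplements the visited thresholds and the best
  visited threshold is returned (ties toward the lower threshold).
  (ii) After an exact match the threshold is re-centred within the
  widest contiguous plateau of thresholds reproducing the manual count
  on the calibration window: a plateau-edge threshold matches the
  window by construction but generalizes poorly to the rest of the
  recording, while the plateau centre is maximally robust to sampling
  noise. `converged` always means the achieved count equals the manual
  count at the returned threshold.
* **Degenerate inputs.** Frames with a near-zero horizontal aperture
  (C ≤ 1e-6 px) or non-finite landmarks are masked, not dropped, so
  indices stay aligned with the video timeline; masked frames break
  runs (a blink cannot span a detection failure). A single missing eye
  degrades to the other eye with a flag. Positive semi-definiteness of
  correlation inputs is checked by eigenvalue non-negativity with
  tolerance −1e-10; |r_XM| = 1 is a collinearity error. With exactly
  one complete 60-s window the sample SD of window counts is undefined
  (n−1 = 0) and reported as 0.0.

## Synthetic data: what it emulates and what it does not

The generator exists so every stage is exercisable with known ground
truth, without any recordings.

* **EAR signal.** Baseline Gaussian noise (sd 0.02) around an open-eye
  plateau of 0.30; each blink is a symmetric V dip to 0.08 at the apex.
  Onsets follow a renewal process — after each dip the next onset waits
  a 500 ms refractory period plus a gamma-distributed gap (shape 4)
  whose mean is tuned so the long-run rate matches `rate_bpm` (default
  15/min, the middle of the typical resting 10–25/min band). Dip
  widths are drawn from a truncated normal (mean 300 ms, sd 50 ms,
  floor 200 ms — spontaneous blinks shorter than ~200 ms are
  essentially absent, and at 30 fps the floor guarantees every dip
  subtends at least 3 frames so its ground truth is well defined).
  Ground-truth events are the runs of the *clean* signal below the
  midpoint threshold (open+closed)/2 — roughly the lower half of each
  dip — so noiseless detection at that threshold recovers them exactly
  by construction. Default duration 300 s at 30 fps. Not emulated:
  drift in the open-eye baseline, partial blinks that do not reach full
  closure, head-pose and lighting artifacts, landmark-jitter noise
  correlated across frames. Passing tests therefore demonstrate the
  correctness of the segmentation/calibration logic under controlled
  conditions, not field robustness to real video.
* **Trait samples.** Multivariate standard normal with a target
  correlation matrix via an eigendecomposition square root. The default
  matrix carries the published zero-order correlations of the five
  trait domains with perceived stress and objective blink rate, plus
  stress × blink = 0.27; the trait × trait correlations are not part of
  that published table and are set to zero (the resulting matrix is
  positive definite, smallest eigenvalue 0.40). Real Likert-derived
  scores are bounded and mildly discrete; the normal emulation matters
  only through its correlation structure, which is what the mediation
  stage consumes.
* **Likert items.** Item = midpoint + loading·(latent − midpoint) +
  Gaussian noise, clipped, rounded, and emitted pre-reversed for
  reverse-keyed items so the scoring module undoes the keying. Loading
  1 with zero noise recovers the latent score up to rounding; loading 0
  removes all shared variance (α ≈ 0). Loadings are uniform across
  items; real instruments have heterogeneous loadings and facet
  structure.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| fps | 30 | frames/s | video convention of the measurement setup |
| min_frames | 2 | frames | rejects single-frame noise; real blinks are ≥200 ms |
| max_duration_ms | 500 | ms | excludes voluntary/prolonged closures |
| calibration interval | [0.05, 0.45] | EAR | spans physiologic mEAR; `auto` uses the signal range |
| max_iter / min_interval | 50 / 1e-4 | — / EAR | bisection stopping rules |
| grid_points | 256 | — | fallback/centering scan resolution |
| open / closed EAR | 0.30 / 0.08 | — | typical open-eye and full-closure ratios |
| noise_sd | 0.02 | EAR | mild landmark jitter |
| rate_bpm | 15 | blinks/min | middle of the resting 10–25 range |
| duration mean/sd/floor | 300 / 50 / 200 | ms | spontaneous-blink duration law |
| refractory_ms | 500 | ms | no physically overlapping blinks |
| bootstrap replicates | 5000 | — | stable 95% percentile endpoints |

## Problem sizes used in the test suite

Segmentation is cross-checked against an independent run-length-encoding
oracle on 1,000 random signals of up to 400 frames; calibration
convergence on 200 seeded 2-min signals; end-to-end count recovery on
100 seeded 5-min recordings; mediation parameter recovery at n = 10,000
over 100 seeds; bootstrap calibration with 500 outer × 2,000 inner
replicates at n = 200. These sizes give stable, reproducible checks at
desk scale.

## Known limitations

* The package consumes landmark or EAR series; face detection and
  landmark regression are out of scope.
* Asymptotic SEM-style standard errors are not replicated (see above).
* The classification rule is a sign/significance heuristic on a single
  triangle; it does not generalize to multiple mediators or latent
  variables.
* Blink-rate SD across 60-s windows requires ≥2 complete windows to be
  informative.
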