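"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators:

* a noisy mean-EAR time series with V-shaped blink dips — a renewal
  (refractory + gamma interval) blink process, truncated-normal blink
  durations, Gaussian baseline noise — returning the frame-exact
  ground-truth events alongside the signal;
* multivariate standard-normal trait/stress/blink samples with a target
  correlation matrix (default: the published zero-order structure of the
  five trait domains, perceived stress and objective blink rate, with the
  unreported trait×trait correlations set to zero);
* keyed Likert item matrices whose latent domain scores are recoverable
  by the scoring module.

All randomness flows through one seeded ``numpy`` generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .detection import BlinkEvent, DEFAULT_MAX_DURATION_MS, DEFAULT_MIN_FRAMES
from .ear import EARSeries
from .psychometrics import ScaleDefinition, reverse_item

__all__ = [
    "SignalSpec",
    "TraitSampleSpec",
    "DEFAULT_TRAIT_CORR",
    "TRAIT_VARIABLES",
    "generate_ear_signal",
    "generate_trait_sample",
    "generate_likert_responses",
]


@dataclass(frozen=True)
class SignalSpec:
    """Parameters of the simulated mean-EAR recording.

    Defaults emulate a resting reading recording: 30 fps, ~5 min, a blink
    rate in the middle of the typical resting 10-25 blinks/min band, blink
    durations around 300 ms (the spontaneous 220-380 ms range), an
    open-eye EAR plateau near 0.30 dipping to 0.08 at full closure, and
    mild per-frame Gaussian noise.
    """

    duration_s: float = 300.0
    fps: float = 30.0
    rate_bpm: float = 15.0
    open_ear_mean: float = 0.30
    closed_ear_mean: float = 0.08
    noise_sd: float = 0.02
    blink_duration_ms_mean: float = 300.0
    blink_duration_ms_sd: float = 50.0
    blink_duration_ms_min: float = 200.0
    refractory_ms: float = 500.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.closed_ear_mean < self.open_ear_mean:
            raise ValueError("closed_ear_mean must be below open_ear_mean")
        for name in ("duration_s", "fps", "rate_bpm", "open_ear_mean",
                     "blink_duration_ms_mean", "blink_duration_ms_sd",
                     "blink_duration_ms_min", "refractory_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0 or self.closed_ear_mean < 0:
            raise ValueError("noise_sd and closed_ear_mean must be non-negative")


def generate_ear_signal(spec: SignalSpec) -> Tuple[EARSeries, List[BlinkEvent]]:
    """Simulate a mean-EAR series plus frame-exact ground-truth blink events.

    Blink onsets follow a renewal process: after each blink the next onset
    waits the refractory period plus a gamma-distributed interval whose
    mean is tuned so the long-run onset rate matches ``rate_bpm``.  Each
    blink is a symmetric V dip from the open plateau to the closed level
    whose full width is the drawn (truncated-normal) blink duration.
    Ground-truth events are the runs of the clean (noise-free) signal
    below the midpoint threshold (open+closed)/2 — roughly the lower half
    of each dip — so detection at that threshold recovers them exactly in
    the noiseless case by construction.
    """
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.duration_s * spec.fps))
    mean_interval_s = 60.0 / spec.rate_bpm
    refractory_s = spec.refractory_ms / 1000.0
    mean_width_s = spec.blink_duration_ms_mean / 1000.0
    gap_mean = mean_interval_s - refractory_s - mean_width_s
    if gap_mean <= 0:
        raise ValueError(
            "infeasible rate/refractory combination: blinks would overlap "
            f"(mean interval {mean_interval_s:.2f}s <= refractory + dip width)"
        )
    gamma_shape = 4.0  # mildly regular renewal process

    # truncated-normal duration law; the physiologic floor also keeps every
    # dip >= 3 frames wide so its ground-truth run is well defined at 30 fps
    lo_ms = max(spec.blink_duration_ms_min, 3.0 / spec.fps * 1000.0)
    a = (lo_ms - spec.blink_duration_ms_mean) / spec.blink_duration_ms_sd
    duration_law = stats.truncnorm(a, np.inf, loc=spec.blink_duration_ms_mean,
                                   scale=spec.blink_duration_ms_sd)

    clean = np.full(n_frames, spec.open_ear_mean)
    mid = (spec.open_ear_mean + spec.closed_ear_mean) / 2.0
    truth: List[BlinkEvent] = []

    t = refractory_s + rng.gamma(gamma_shape, gap_mean / gamma_shape)
    while True:
        dur_ms = float(duration_law.rvs(random_state=rng))
        half = max(2, int(round(dur_ms / 1000.0 * spec.fps / 2.0)))
        start = int(round(t * spec.fps))
        width = 2 * half + 1  # apex-centred triangle spanning the drawn duration
        if start + width > n_frames:
            break
        frac = 1.0 - np.abs(np.arange(width) - half) / half
        dip = spec.open_ear_mean - frac * (spec.open_ear_mean - spec.closed_ear_mean)
        clean[start:start + width] = np.minimum(clean[start:start + width], dip)
        t += width / spec.fps + refractory_s + rng.gamma(gamma_shape, gap_mean / gamma_shape)

    # ground truth: runs of the clean signal strictly below the midpoint
    below = clean < mid
    padded = np.concatenate(([False], below, [False])).astype(np.int8)
    d = np.diff(padded)
    for on, off in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1) - 1):
        n = int(off - on + 1)
        ms = n / spec.fps * 1000.0
        truth.append(BlinkEvent(int(on), int(off), float(ms),
                                bool(n >= DEFAULT_MIN_FRAMES and ms <= DEFAULT_MAX_DURATION_MS)))

    values = np.clip(clean + rng.normal(0.0, spec.noise_sd, n_frames), 0.0, None)
    return EARSeries(values, fps=spec.fps), truth


# ---------------------------------------------------------------------------
# correlated trait / stress / blink samples

TRAIT_VARIABLES = (
    "extraversion",
    "agreeableness",
    "conscientiousness",
    "negative_emotionality",
    "open_mindedness",
    "stress",
    "objective_blink",
)

# Zero-order structure of the published trait/stress/blink correlations.
# Trait-trait cells are not reported and default to zero (PSD verified).
_trait_stress = (-0.033, -0.16, -0.26, 0.35, -0.10)
_trait_blink = (0.05, -0.07, 0.001, -0.17, -0.21)


def _default_corr() -> np.ndarray:
    r = np.eye(7)
    for i in range(5):
        r[i, 5] = r[5, i] = _trait_stress[i]
        r[i, 6] = r[6, i] = _trait_blink[i]
    r[5, 6] = r[6, 5] = 0.27
    return r


DEFAULT_TRAIT_CORR: np.ndarray = _default_corr()


@dataclass(frozen=True)
class TraitSampleSpec:
    """Target correlation matrix, sample size and seed for the trait sampler."""

    n: int
    corr: np.ndarray = field(default_factory=_default_corr)
    variables: Tuple[str, ...] = TRAIT_VARIABLES
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        c = np.asarray(self.corr, dtype=float)
        object.__setattr__(self, "corr", c)
        if self.n < 3:
            raise ValueError("n too small: need at least 3 for correlations")
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("correlation matrix must be square")
        if len(self.variables) != c.shape[0]:
            raise ValueError("variable names must match matrix dimension")
        if not np.allclose(c, c.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.min(np.linalg.eigvalsh(c)) < -1e-10:
            raise ValueError("correlation matrix is not positive semi-definite")


def generate_trait_sample(spec: TraitSampleSpec) -> pd.DataFrame:
    """Draw standardized multivariate-normal samples with the target correlation.

    Uses an eigendecomposition square root (valid for semi-definite
    targets); sample correlations converge to the target as n grows.
    """
    w, v = np.linalg.eigh(spec.corr)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n, spec.corr.shape[0]))
    return pd.DataFrame(z @ root.T, columns=list(spec.variables))


def generate_likert_responses(
    domain_scores: Sequence[float],
    definition: ScaleDefinition,
    loading: float = 1.0,
    noise_sd: float = 0.5,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Emit a keyed integer item matrix whose scoring recovers the latent scores.

    Each item is the latent score shrunk toward the scale midpoint by
    ``loading`` plus Gaussian noise, clipped to the response range and
    rounded; reverse-keyed items are emitted pre-reversed so that
    ``score_scale`` undoes the keying.  ``loading`` in [0, 1]: 1 passes
    the latent score through (exact recovery at zero noise), 0 removes
    all shared variance (internal consistency collapses to ~0).
    """
    if not 0.0 <= loading <= 1.0:
        raise ValueError("loading must lie in [0, 1]")
    scores = np.asarray(domain_scores, dtype=float)
    lo, hi = definition.response_min, definition.response_max
    if np.any((scores < lo) | (scores > hi)):
        raise ValueError(f"domain scores outside response range [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    mid = (lo + hi) / 2.0
    k = definition.item_count
    latent = mid + loading * (scores[:, None] - mid)
    raw = latent + rng.normal(0.0, noise_sd, size=(scores.size, k))
    items = np.clip(np.rint(np.clip(raw, lo, hi)), lo, hi)
    for j in definition.reverse_keyed_items:
        items[:, j - 1] = lo + hi - items[:, j - 1]
    return items
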