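"""Personalized mEAR-threshold calibration by bisection.

The blink detector needs a per-participant threshold: lid geometry and
camera angle shift the open-eye EAR baseline between individuals.  The
calibration searches, by interval halving, for the threshold at which the
automatic blink count on a calibration window (conventionally the first
two minutes of the recording) matches a manual count made by a human
rater.  Because the below-threshold frame set grows monotonically with
the threshold, raising the threshold when the automatic count falls short
brackets the matching count.  The blink *count* itself is not strictly
monotone (adjacent runs can merge, and very wide runs trip the maximum-
duration exclusion), so when bisection fails to match exactly a fine grid
scan of the initial interval supplements the visited thresholds; the
result is the visited threshold minimizing the count discrepancy, ties
broken toward the lower threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Tuple, Union

import numpy as np

from .detection import DEFAULT_MAX_DURATION_MS, DEFAULT_MIN_FRAMES, detect_blinks
from .ear import EARSeries

__all__ = ["CalibrationResult", "calibrate_threshold", "DEFAULT_INTERVAL"]

#: default search interval spanning physiologic EAR values
DEFAULT_INTERVAL: Tuple[float, float] = (0.05, 0.45)


class TraceStep(NamedTuple):
    lo: float
    hi: float
    mid: float
    auto_count: int


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the bisection search, with a full iteration trace for audit."""

    threshold: float
    iterations: int
    achieved_count: int
    manual_count: int
    converged: bool
    trace: List[TraceStep]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "threshold": self.threshold,
                    "iterations": self.iterations,
                    "achieved_count": self.achieved_count,
                    "manual_count": self.manual_count,
                    "converged": self.converged,
                    "trace": [t._asdict() for t in self.trace],
                },
                fh,
                indent=2,
            )


def _count_valid(series: EARSeries, threshold: float, min_frames: int, max_duration_ms: float) -> int:
    return sum(e.valid for e in detect_blinks(series, threshold, min_frames, max_duration_ms))


def calibrate_threshold(
    series: EARSeries,
    manual_count: int,
    interval: Union[Tuple[float, float], str] = DEFAULT_INTERVAL,
    max_iter: int = 50,
    min_interval: float = 1e-4,
    min_frames: int = DEFAULT_MIN_FRAMES,
    max_duration_ms: float = DEFAULT_MAX_DURATION_MS,
    grid_points: int = 256,
) -> CalibrationResult:
    """Bisection search for the threshold matching a manual blink count.

    Parameters
    ----------
    series
        Calibration window of the mEAR signal (>= 60 s).
    manual_count
        Human-annotated number of blinks in the window.
    interval
        ``(lo, hi)`` initial search interval, or ``"auto"`` to use the
        observed signal range.
    max_iter, min_interval
        Stopping rules: iteration cap and minimal bracket width.

    At each step the automatic count at the interval midpoint is compared
    with the manual count; a shortfall raises the lower limit, an excess
    lowers the upper limit, halving the bracket.  Convergence means exact
    count agreement.  Because the valid-blink count is not strictly
    monotone in the threshold, a bisection run that terminates without an
    exact match is followed by a scan over ``grid_points`` thresholds in
    the initial interval; the best threshold visited by either search is
    returned (``converged`` reflects exact agreement).  A manual count
    beyond the reach of any threshold yields ``converged=False``, never
    an exception.
    """
    if manual_count < 0:
        raise ValueError("manual_count must be non-negative")
    if series.duration_s < 60.0:
        raise ValueError("calibration window must cover at least 60 s")
    if interval == "auto":
        vals = series.values[~series.mask]
        lo, hi = float(np.min(vals)), float(np.max(vals))
    else:
        lo, hi = float(interval[0]), float(interval[1])
    if not (0 <= lo < hi):
        raise ValueError(f"invalid interval [{lo}, {hi}]")

    trace: List[TraceStep] = []
    best_mid: Optional[float] = None
    best_count = 0
    best_err = np.inf

    converged = False
    threshold = (lo + hi) / 2.0
    achieved = -1
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        auto = _count_valid(series, mid, min_frames, max_duration_ms)
        trace.append(TraceStep(lo, hi, mid, auto))
        err = abs(auto - manual_count)
        if err < best_err or (err == best_err and mid < best_mid):
            best_err, best_mid, best_count = err, mid, auto
        if auto == manual_count:
            converged = True
            threshold, achieved = mid, auto
            break
        if auto < manual_count:
            lo = mid
        else:
            hi = mid
        if hi - lo < min_interval:
            break

    lo0, hi0 = trace[0].lo, trace[0].hi
    grid = np.linspace(lo0, hi0, grid_points)[1:]
    if not converged:
        # grid-scan fallback: the count staircase is not monotone, so the
        # bisection bracket may have walked away from the matching plateau
        for mid in grid:
            auto = _count_valid(series, float(mid), min_frames, max_duration_ms)
            err = abs(auto - manual_count)
            if err < best_err or (err == best_err and mid < best_mid):
                best_err, best_mid, best_count = err, float(mid), auto
        threshold, achieved = best_mid, best_count
        converged = achieved == manual_count
    if converged:
        # center the threshold within the widest exact-match plateau: a
        # threshold at a plateau edge matches the calibration window but
        # generalizes poorly to the rest of the recording
        exact = np.array([
            _count_valid(series, float(g), min_frames, max_duration_ms) == manual_count
            for g in grid
        ])
        if exact.any():
            padded = np.concatenate(([False], exact, [False])).astype(np.int8)
            d = np.diff(padded)
            starts = np.flatnonzero(d == 1)
            ends = np.flatnonzero(d == -1) - 1
            widest = int(np.argmax(ends - starts))
            centre = float(grid[(starts[widest] + ends[widest]) // 2])
            auto = _count_valid(series, centre, min_frames, max_duration_ms)
            if auto == manual_count:  # guard against grid raggedness
                threshold, achieved = centre, auto

    return CalibrationResult(
        threshold=float(threshold),
        iterations=len(trace),
        achieved_count=int(achieved),
        manual_count=int(manual_count),
        converged=converged,
        trace=trace,
    )
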