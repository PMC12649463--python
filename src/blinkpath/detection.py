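"""Blink segmentation and per-minute rate statistics.

A blink event is a maximal run of consecutive unmasked frames whose mean
EAR falls below a (calibrated) threshold.  Durations follow from run
length and frame rate; events longer than a configurable maximum
(default 500 ms) are retained for audit but flagged invalid and excluded
from rate statistics, filtering voluntary or prolonged closures.  The
outcome measure is the mean and standard deviation of blink counts over
complete non-overlapping 60-s windows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

from .ear import EARSeries

__all__ = [
    "BlinkEvent",
    "BlinkSummary",
    "detect_blinks",
    "blink_rate_stats",
    "events_to_csv",
    "events_from_csv",
    "summary_to_json",
]

DEFAULT_MIN_FRAMES = 2          # rejects single-frame noise (~67 ms at 30 fps)
DEFAULT_MAX_DURATION_MS = 500.0  # excludes voluntary / prolonged closures


@dataclass(frozen=True)
class BlinkEvent:
    """One detected lid closure: inclusive frame run with duration and validity."""

    onset_frame: int
    offset_frame: int
    duration_ms: float
    valid: bool

    @property
    def n_frames(self) -> int:
        return self.offset_frame - self.onset_frame + 1


@dataclass(frozen=True)
class BlinkSummary:
    """Per-minute blink-rate statistics over complete 60-s windows."""

    mean_bpm: float
    sd_bpm: float
    n_events: int
    n_excluded: int
    total_minutes: float


def detect_blinks(
    series: EARSeries,
    threshold: float,
    min_frames: int = DEFAULT_MIN_FRAMES,
    max_duration_ms: float = DEFAULT_MAX_DURATION_MS,
) -> List[BlinkEvent]:
    """Segment blink events as maximal sub-threshold runs of the mEAR signal.

    Masked frames break runs (a blink cannot span a detection failure).
    Runs shorter than ``min_frames`` are discarded as noise; runs longer
    than ``max_duration_ms`` are returned with ``valid=False`` so they are
    excluded from rate statistics yet auditable.  Events are disjoint and
    ordered by onset.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")
    if np.all(series.mask):
        warnings.warn("fully masked series: no frames available for detection")
        return []

    below = (series.values < threshold) & ~series.mask
    # run-length segmentation on the boolean vector
    padded = np.concatenate(([False], below, [False])).astype(np.int8)
    d = np.diff(padded)
    onsets = np.flatnonzero(d == 1)
    offsets = np.flatnonzero(d == -1) - 1

    events: List[BlinkEvent] = []
    for on, off in zip(onsets, offsets):
        n = int(off - on + 1)
        if n < min_frames:
            continue
        duration_ms = n / series.fps * 1000.0
        events.append(
            BlinkEvent(int(on), int(off), float(duration_ms), bool(duration_ms <= max_duration_ms))
        )
    return events


def blink_rate_stats(events: Sequence[BlinkEvent], series: EARSeries) -> BlinkSummary:
    """Mean and sample SD of valid-blink counts over complete 60-s windows.

    The recording is tiled into non-overlapping 60-s windows; a valid event
    belongs to the window containing its onset; a partial trailing window
    is dropped.  With a single complete window the sample SD is undefined
    and reported as 0.0.
    """
    frames_per_window = int(round(series.fps * 60.0))
    n_windows = len(series) // frames_per_window
    if n_windows < 1:
        raise ValueError("recording too short for per-minute statistics")

    counts = np.zeros(n_windows, dtype=int)
    n_valid: int = 0
    n_excluded: int = 0
    for ev in events:
        if not ev.valid:
            n_excluded += 1
            continue
        n_valid += 1
        w = ev.onset_frame // frames_per_window
        if w < n_windows:
            counts[w] += 1

    sd = float(np.std(counts, ddof=1)) if n_windows > 1 else 0.0
    return BlinkSummary(
        mean_bpm=float(np.mean(counts)),
        sd_bpm=sd,
        n_events=n_valid,
        n_excluded=n_excluded,
        total_minutes=float(n_windows),
    )


# ---------------------------------------------------------------------------
# external interfaces


def events_to_csv(events: Sequence[BlinkEvent], path) -> None:
    pd.DataFrame(
        [
            {
                "onset_frame": e.onset_frame,
                "offset_frame": e.offset_frame,
                "duration_ms": e.duration_ms,
                "valid": e.valid,
            }
            for e in events
        ],
        columns=["onset_frame", "offset_frame", "duration_ms", "valid"],
    ).to_csv(path, index=False)


def events_from_csv(path) -> List[BlinkEvent]:
    df = pd.read_csv(path)
    return [
        BlinkEvent(int(r.onset_frame), int(r.offset_frame), float(r.duration_ms), bool(r.valid))
        for r in df.itertuples()
    ]


def summary_to_json(summary: BlinkSummary, path, threshold: float) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "mean_bpm": summary.mean_bpm,
                "sd_bpm": summary.sd_bpm,
                "n_events": summary.n_events,
                "n_excluded": summary.n_excluded,
                "total_minutes": summary.total_minutes,
                "threshold": threshold,
            },
            fh,
            indent=2,
        )
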