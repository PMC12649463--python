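"""Eye-aspect-ratio (EAR) computation from 6-point eye landmarks.

The EAR of one eye is (A + B) / (2 C), where A and B are the two vertical
lid openings and C is the horizontal aperture of the standard 6-point eye
contour (68-point facial-landmark convention: p1 temporal corner, p4 nasal
corner, p2/p3 upper lid, p6/p5 lower lid).  The ratio is dimensionless,
drops toward zero during lid closure, and is invariant to translation,
rotation and uniform scaling of the landmark set.  The detection signal is
the per-frame arithmetic mean of the two eyes (mEAR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "EyeLandmarkSet",
    "EARSeries",
    "MeanEar",
    "compute_ear",
    "mean_ear",
    "series_from_landmarks",
    "read_landmarks_csv",
    "read_ear_csv",
]

#: below this horizontal aperture (pixels) a frame is treated as degenerate
DEFAULT_C_EPSILON = 1e-6


@dataclass(frozen=True)
class EyeLandmarkSet:
    """Six planar landmarks of one eye, in pixel units.

    Points follow the 68-point facial-landmark ordering: ``p1`` temporal
    corner, ``p2``/``p3`` upper lid, ``p4`` nasal corner, ``p5``/``p6``
    lower lid.  Stored as a ``(6, 2)`` float array.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (6, 2):
            raise ValueError(f"expected 6 planar points, got array of shape {pts.shape}")
        object.__setattr__(self, "points", pts)

    @classmethod
    def from_points(cls, p1, p2, p3, p4, p5, p6) -> "EyeLandmarkSet":
        return cls(np.array([p1, p2, p3, p4, p5, p6], dtype=float))

    def __getattr__(self, name: str):
        # p1..p6 attribute access
        if len(name) == 2 and name[0] == "p" and name[1] in "123456":
            return self.points[int(name[1]) - 1]
        raise AttributeError(name)


class MeanEar(NamedTuple):
    """Per-frame mean EAR with a single-eye degradation flag."""

    value: float
    single_eye: bool


def compute_ear(eye: EyeLandmarkSet, eps: float = DEFAULT_C_EPSILON) -> float:
    """Eye aspect ratio (A + B) / (2 C) of one eye.

    A = |p2 − p6| and B = |p3 − p5| are the vertical lid openings,
    C = |p1 − p4| the horizontal aperture.  A frame whose horizontal
    aperture is degenerate (C ≤ ``eps``) or whose coordinates are not
    finite yields ``nan`` — the caller masks the frame rather than
    aborting the run.
    """
    pts = eye.points
    if not np.all(np.isfinite(pts)):
        return math.nan
    a = float(np.linalg.norm(pts[1] - pts[5]))
    b = float(np.linalg.norm(pts[2] - pts[4]))
    c = float(np.linalg.norm(pts[0] - pts[3]))
    if c <= eps:
        return math.nan
    return (a + b) / (2.0 * c)


def mean_ear(left: float, right: float) -> MeanEar:
    """Arithmetic mean of the two per-eye EAR values (mEAR).

    Missing eyes are encoded as ``nan``.  With exactly one eye missing the
    other value is passed through and the frame is flagged ``single_eye``;
    with both missing the result is ``nan`` (a masked frame).  Symmetric
    in its arguments.
    """
    l_ok = left is not None and not math.isnan(left)
    r_ok = right is not None and not math.isnan(right)
    if l_ok and r_ok:
        return MeanEar((left + right) / 2.0, False)
    if l_ok:
        return MeanEar(float(left), True)
    if r_ok:
        return MeanEar(float(right), True)
    return MeanEar(math.nan, False)


@dataclass
class EARSeries:
    """Per-frame mean-EAR signal with fps metadata and a missing-frame mask.

    ``values`` holds one dimensionless mEAR scalar per frame (``nan`` where
    masked); ``mask`` is True for frames where detection failed on both
    eyes; ``single_eye`` marks frames computed from one eye only.
    """

    values: np.ndarray
    fps: float = 30.0
    mask: Optional[np.ndarray] = None
    single_eye: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("EARSeries requires a non-empty 1-d value sequence")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.mask is None:
            self.mask = np.isnan(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask length must match values")
        if self.single_eye is None:
            self.single_eye = np.zeros_like(self.mask)
        else:
            self.single_eye = np.asarray(self.single_eye, dtype=bool)
        valid = self.values[~self.mask]
        if valid.size and np.any(valid < 0):
            raise ValueError("EAR values must be non-negative where not masked")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fps

    def slice_seconds(self, start_s: float, end_s: float) -> "EARSeries":
        """Sub-series covering ``[start_s, end_s)`` of the recording."""
        i = int(round(start_s * self.fps))
        j = int(round(end_s * self.fps))
        if not 0 <= i < j <= len(self):
            raise ValueError(f"window [{start_s}, {end_s}) s outside recording")
        return EARSeries(self.values[i:j], self.fps, self.mask[i:j], self.single_eye[i:j])


def series_from_landmarks(
    frames: Sequence[Tuple[Optional[EyeLandmarkSet], Optional[EyeLandmarkSet]]],
    fps: float = 30.0,
    eps: float = DEFAULT_C_EPSILON,
) -> EARSeries:
    """Build an :class:`EARSeries` from per-frame (left, right) landmark sets.

    Length-preserving: element *i* is ``mean_ear(compute_ear(left_i),
    compute_ear(right_i))``.  Frames with degenerate or absent landmarks on
    both eyes are masked, keeping indices aligned with the video timeline.
    """
    frames = list(frames)
    if len(frames) == 0:
        raise ValueError("empty recording")
    values = np.empty(len(frames))
    single = np.zeros(len(frames), dtype=bool)
    for i, (left, right) in enumerate(frames):
        l = compute_ear(left, eps) if left is not None else math.nan
        r = compute_ear(right, eps) if right is not None else math.nan
        m = mean_ear(l, r)
        values[i] = m.value
        single[i] = m.single_eye
    return EARSeries(values, fps=fps, single_eye=single)


# ---------------------------------------------------------------------------
# CSV interfaces


def read_landmarks_csv(path, fps: float = 30.0, eps: float = DEFAULT_C_EPSILON) -> EARSeries:
    """Read a landmark CSV (``frame, lx1..ly6, rx1..ry6``) into an EARSeries."""
    df = pd.read_csv(path)
    lcols = [f"l{a}{i}" for i in range(1, 7) for a in ("x", "y")]
    rcols = [f"r{a}{i}" for i in range(1, 7) for a in ("x", "y")]
    missing = [c for c in ["frame", *lcols, *rcols] if c not in df.columns]
    if missing:
        raise ValueError(f"landmark CSV missing columns: {missing}")
    df = df.sort_values("frame")
    frames = []
    for _, row in df.iterrows():
        left = EyeLandmarkSet(row[lcols].to_numpy(dtype=float).reshape(6, 2))
        right = EyeLandmarkSet(row[rcols].to_numpy(dtype=float).reshape(6, 2))
        frames.append((left, right))
    return series_from_landmarks(frames, fps=fps, eps=eps)


def read_ear_csv(path, fps: float = 30.0) -> EARSeries:
    """Read a precomputed EAR CSV.

    Accepts either ``frame, ear_left, ear_right`` or ``frame, mear``
    columns; empty cells denote missing values.
    """
    df = pd.read_csv(path).sort_values("frame")
    if "mear" in df.columns:
        return EARSeries(df["mear"].to_numpy(dtype=float), fps=fps)
    if {"ear_left", "ear_right"}.issubset(df.columns):
        values = np.empty(len(df))
        single = np.zeros(len(df), dtype=bool)
        left = df["ear_left"].to_numpy(dtype=float)
        right = df["ear_right"].to_numpy(dtype=float)
        for i in range(len(df)):
            m = mean_ear(left[i], right[i])
            values[i] = m.value
            single[i] = m.single_eye
        return EARSeries(values, fps=fps, single_eye=single)
    raise ValueError("EAR CSV needs either a 'mear' or 'ear_left'/'ear_right' columns")


def write_ear_csv(series: EARSeries, path) -> None:
    """Write the mean-EAR signal as ``frame, mear`` (masked frames empty)."""
    vals = series.values.copy()
    vals[series.mask] = np.nan
    pd.DataFrame({"frame": np.arange(len(series)), "mear": vals}).to_csv(path, index=False)
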