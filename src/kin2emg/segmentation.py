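"""Submovement segmentation at inflection points of the speed profile.

Movements are decomposed into sub-sequences wherever the second derivative
of the end-effector speed changes sign (bell-shaped acceleration units),
bounded by a relative velocity threshold that defines the active interval.
A single minimum-jerk stroke has exactly two such inflection points, at
tau = (3 +/- sqrt(3)) / 6 of the stroke, and therefore yields three
segments; multi-stroke (complex) movements yield more.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class SegmentationResult:
    """Active interval, inflection indices, and the resulting partition.

    ``segments`` are half-open frame ranges covering every sustained
    above-threshold run; for a continuous movement (one run — the usual
    case for the study's tasks) they partition the active interval exactly.
    A mid-trial pause splits the movement into runs that are segmented
    independently, with the below-threshold dwell excluded.
    """

    active_interval: tuple  # (start, stop_exclusive) frame indices
    inflection_indices: np.ndarray  # sorted, strictly inside the runs
    boundaries: np.ndarray  # run edges + inflections
    segments: list  # list of (lo, hi) half-open frame ranges

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def covered_frames(self) -> np.ndarray:
        return np.concatenate([np.arange(lo, hi) for lo, hi in self.segments])


def speed_profile(eef_positions: np.ndarray, rate: float) -> np.ndarray:
    """Smoothed end-effector speed (m/s) per frame.

    Central-difference velocity magnitude followed by a 5-frame zero-phase
    moving average (symmetric FIR, reflected edges).
    """
    pos = np.asarray(eef_positions, dtype=float)
    if len(pos) < 5:
        raise ValueError("need at least 5 frames")
    vel = np.gradient(pos, 1.0 / rate, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    padded = np.pad(speed, 2, mode="reflect")
    kernel = np.ones(5) / 5.0
    return np.convolve(padded, kernel, mode="valid")


def find_inflection_points(
    speed: np.ndarray, min_gap: int = 6, curvature_tol_rel: float = 1e-8
) -> np.ndarray:
    """Frames where the discrete second derivative of speed changes sign.

    Detections closer than ``min_gap`` frames are merged to the first of
    the cluster; curvature below ``curvature_tol_rel * max(speed)`` counts
    as zero (floating-point noise on flat stretches is not an inflection).
    An empty result is allowed (e.g. strictly convex speed).
    """
    speed = np.asarray(speed, dtype=float)
    d2 = np.diff(speed, 2)  # d2[i] is the curvature at frame i + 1
    tol = curvature_tol_rel * max(float(np.abs(speed).max()), 1e-300)
    sign = np.sign(d2)
    sign[np.abs(d2) < tol] = 0.0
    idx = []
    prev_sign = 0.0
    for i, s in enumerate(sign):
        if s == 0.0:
            continue
        if prev_sign != 0.0 and s != prev_sign:
            idx.append(i + 1)
        prev_sign = s
    if not idx:
        return np.array([], dtype=int)
    merged = [idx[0]]
    for i in idx[1:]:
        if i - merged[-1] >= min_gap:
            merged.append(i)
    return np.asarray(merged, dtype=int)


def _sustained_runs(mask: np.ndarray, min_len: int) -> list:
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            if i - start >= min_len:
                runs.append((start, i))
            start = None
    if start is not None and len(mask) - start >= min_len:
        runs.append((start, len(mask)))
    return runs


def segment_movement(
    eef_positions: np.ndarray,
    rate: float = 60.0,
    theta_rel: float = 0.05,
    min_gap: float = 0.1,
    sustain: int = 3,
) -> SegmentationResult:
    """Partition a movement into sub-sequences at speed inflection points.

    The active interval runs from the first to the last sustained crossing
    of ``theta_rel * max(speed)`` (``sustain`` consecutive frames above the
    threshold); boundaries are the interval start, the inflection points
    strictly inside it, and the interval stop. Because the threshold is
    relative, the segmentation is invariant to a global rescaling of the
    positions. If the speed never sustains above the threshold, the whole
    trial becomes one degenerate segment (with a warning).
    """
    speed = speed_profile(eef_positions, rate)
    peak = speed.max()
    if peak <= 0:
        runs = []
    else:
        runs = _sustained_runs(speed >= theta_rel * peak, sustain)
    n = len(speed)
    if not runs:
        warnings.warn(
            "speed never sustained above threshold: single degenerate segment",
            stacklevel=2,
        )
        return SegmentationResult(
            active_interval=(0, n),
            inflection_indices=np.array([], dtype=int),
            boundaries=np.array([0, n]),
            segments=[(0, n)],
        )
    gap_frames = max(1, int(round(min_gap * rate)))
    infl_all = find_inflection_points(speed, min_gap=gap_frames)
    segments = []
    boundaries = []
    kept_infl = []
    for lo, hi in runs:
        infl = infl_all[(infl_all > lo) & (infl_all < hi - 1)]
        kept_infl.extend(infl.tolist())
        bounds = np.concatenate([[lo], infl, [hi]])
        boundaries.extend(bounds.tolist())
        segments.extend(zip(bounds[:-1], bounds[1:]))
    return SegmentationResult(
        active_interval=(runs[0][0], runs[-1][1]),
        inflection_indices=np.asarray(kept_infl, dtype=int),
        boundaries=np.asarray(sorted(set(boundaries)), dtype=int),
        segments=[(int(a), int(b)) for a, b in segments],
    )
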