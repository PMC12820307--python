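"""EMG enveloping, session normalization, and kinematic scaling.

Raw EMG (2222 Hz) is synchronized to the kinematic clock (60 Hz) by taking
the root mean square of all samples inside a 200 ms window centered on each
kinematic timestamp — smoothing and downsampling in one step. Envelopes are
then normalized per subject and channel by the session-wide maximum so
values lie in [0, 1]; kinematic position features are min-max scaled to
[-1, 1] over the same session scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np



class EmptyWindowError(ValueError):
    """A resampling window contained no raw EMG samples."""


class DegenerateRecordingError(ValueError):
    """A channel is identically zero over the whole session."""


@dataclass
class ProcessedTrial:
    """A trial after enveloping/normalization, aligned to the kinematic clock."""

    kin_timestamps: np.ndarray
    emg_envelope: np.ndarray  # (N, 8), normalized to [0, 1]
    envelope_raw: np.ndarray  # (N, 8), pre-normalization RMS


def rms_resample(
    raw_emg: np.ndarray,
    raw_timestamps: np.ndarray,
    target_timestamps: np.ndarray,
    window: float = 0.200,
) -> np.ndarray:
    """Windowed RMS of raw EMG at each target timestamp.

    For target time t, ``value_c = sqrt(mean(x_c[i]^2))`` over all raw
    samples with ``|t_i - t| <= window / 2`` (closed interval; edge windows
    use whatever samples are available). Raises :class:`EmptyWindowError`
    naming the frame index if a window is empty.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    arr = np.asarray(raw_emg, dtype=float)
    one_d = arr.ndim == 1
    raw = arr[:, None] if one_d else arr
    t_raw = np.asarray(raw_timestamps, dtype=float)
    if raw.shape[0] != t_raw.shape[0]:
        raise ValueError("raw_emg and raw_timestamps length mismatch")
    if np.any(np.diff(t_raw) < 0):
        raise ValueError("raw timestamps must be sorted")
    t_out = np.asarray(target_timestamps, dtype=float)

    css = np.concatenate([np.zeros((1, raw.shape[1])), np.cumsum(raw**2, axis=0)])
    half = window / 2.0
    lo = np.searchsorted(t_raw, t_out - half, side="left")
    hi = np.searchsorted(t_raw, t_out + half, side="right")
    counts = hi - lo
    empty = np.nonzero(counts == 0)[0]
    if empty.size:
        raise EmptyWindowError(
            f"no raw EMG samples within the window of frame {empty[0]}"
        )
    mean_sq = (css[hi] - css[lo]) / counts[:, None]
    out = np.sqrt(mean_sq)
    return out[:, 0] if one_d else out


def normalize_emg_session(envelopes: list) -> tuple:
    """Scale all trials of one subject by per-channel session maxima.

    Parameters
    ----------
    envelopes : list of (N_i, C) arrays
        Pre-normalization envelopes for every trial in the session.

    Returns
    -------
    normalized : list of arrays (same shapes)
    maxima : (C,) array of the session-wide per-channel maxima used.
    """
    if not envelopes:
        raise ValueError("need at least one trial")
    maxima = np.max([e.max(axis=0) for e in envelopes], axis=0)
    if np.any(maxima <= 0):
        bad = int(np.argmax(maxima <= 0))
        raise DegenerateRecordingError(f"channel {bad} is all-zero over the session")
    return [e / maxima for e in envelopes], maxima


@dataclass
class KinematicScaling:
    """Per-subject-session min-max record for position features."""

    pos_min: np.ndarray  # (3,)
    pos_max: np.ndarray  # (3,)

    def apply(self, positions: np.ndarray) -> np.ndarray:
        span = self.pos_max - self.pos_min
        out = np.zeros_like(positions, dtype=float)
        ok = span > 0
        out[:, ok] = 2.0 * (positions[:, ok] - self.pos_min[ok]) / span[ok] - 1.0
        return out


def scale_kinematics_session(position_series: list) -> tuple:
    """Fit the session [-1, 1] scaling for end-effector positions.

    Each position axis is mapped by ``x -> 2 (x - min) / (max - min) - 1``
    with min/max taken over the whole subject session. Quaternion
    components are deliberately not rescaled (they already live in [-1, 1]
    and min-max scaling would distort rotation geometry); the swivel angle
    has its own fixed mapping (see :func:`kin2emg.arm_geometry.scale_swivel`).

    Returns ``(scaled_list, record)``. A constant axis maps to 0 and emits
    a warning.
    """
    if not position_series:
        raise ValueError("need at least one trial")
    stacked = np.vstack(position_series)
    rec = KinematicScaling(pos_min=stacked.min(axis=0), pos_max=stacked.max(axis=0))
    if np.any(rec.pos_max - rec.pos_min <= 0):
        warnings.warn("constant position feature mapped to 0", stacklevel=2)
    return [rec.apply(p) for p in position_series], rec


def preprocess_subject_envelopes(trials: list, window: float = 0.200) -> tuple:
    """RMS-resample and session-normalize all trials of one subject.

    Returns ``(processed, maxima)`` where ``processed`` is a list of
    :class:`ProcessedTrial` in trial order.
    """
    raw_env = [
        rms_resample(t.raw_emg, t.emg_timestamps, t.kin_timestamps, window)
        for t in trials
    ]
    normalized, maxima = normalize_emg_session(raw_env)
    processed = [
        ProcessedTrial(
            kin_timestamps=t.kin_timestamps, emg_envelope=n, envelope_raw=r
        )
        for t, n, r in zip(trials, normalized, raw_env)
    ]
    return processed, maxima
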