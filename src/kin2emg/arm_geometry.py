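"""Swivel-angle geometry and model feature assembly.

The swivel angle parameterizes the redundant rotational degree of freedom
of the elbow about the shoulder-wrist axis: it is the angle between the arm
plane (through shoulder S, elbow E, wrist W) and a reference plane through
S and W. With the classic vertical-axis reference the angle is

    cos(alpha) = (n_A . n_R) / (|n_A| |n_R|),
    n_A = (E - S) x (W - S),   n_R = (W - S) x z_hat,

zero when the elbow lies directly below the shoulder-wrist line. That
reference degenerates when the wrist is straight below (or above) the
shoulder — exactly the resting position of every task here — so the elbow
swivel angle (ESA) replaces z_hat by a help vector that starts as the
x-axis and is transported along with the shoulder-wrist direction, keeping
the reference plane defined throughout the motion.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np


class DegenerateReferenceError(ValueError):
    """Shoulder-wrist axis (anti)parallel to the vertical reference."""


class StraightArmError(ValueError):
    """Elbow lies on the shoulder-wrist line: arm plane undefined."""


class DegeneracyReason(str, Enum):
    NONE = "none"
    WRIST_OVER_SHOULDER = "wrist_over_shoulder"
    STRAIGHT_ARM = "straight_arm"


DEFAULT_EPS_AXIS = float(np.sin(np.deg2rad(2.0)))


def swivel_angle_z(S, E, W, eps_axis: float = DEFAULT_EPS_AXIS) -> float:
    """Swivel angle against the fixed vertical-axis reference plane.

    Returns the unsigned angle in [0, pi]; 0 when the elbow is directly
    below the shoulder-wrist line. Raises
    :class:`DegenerateReferenceError` when the shoulder-wrist direction is
    within ``asin(eps_axis)`` of vertical, and :class:`StraightArmError`
    when the elbow is (numerically) on the shoulder-wrist line.
    """
    S, E, W = (np.asarray(v, dtype=float) for v in (S, E, W))
    sw = W - S
    sw_norm = np.linalg.norm(sw)
    if sw_norm == 0:
        raise DegenerateReferenceError("wrist coincides with shoulder")
    n_r = np.cross(sw, [0.0, 0.0, 1.0])
    if np.linalg.norm(n_r) < eps_axis * sw_norm:
        raise DegenerateReferenceError(
            "shoulder-wrist axis (anti)parallel to z: reference plane undefined"
        )
    n_a = np.cross(E - S, sw)
    n_a_norm = np.linalg.norm(n_a)
    if n_a_norm < 1e-9 * sw_norm * max(np.linalg.norm(E - S), 1e-12):
        raise StraightArmError("elbow on the shoulder-wrist line: arm plane undefined")
    cos_a = np.dot(n_a, n_r) / (n_a_norm * np.linalg.norm(n_r))
    return float(np.arccos(np.clip(cos_a, -1.0, 1.0)))


@dataclass
class SwivelSeries:
    """Per-frame elbow swivel angle with validity flags and help-vector state."""

    angle: np.ndarray  # (N,) radians in [0, pi]
    valid: np.ndarray  # (N,) bool
    help_vector: np.ndarray  # (N, 3) unit vectors, orthogonal to shoulder->wrist
    degeneracy_reason: list  # (N,) DegeneracyReason


def _rotate_minimal(v: np.ndarray, u_from: np.ndarray, u_to: np.ndarray) -> np.ndarray:
    """Apply the minimal rotation taking u_from to u_to (Rodrigues)."""
    axis = np.cross(u_from, u_to)
    s = np.linalg.norm(axis)
    c = float(np.dot(u_from, u_to))
    if s < 1e-12:
        if c < 0:  # antipodal flip within one frame: no unique minimal rotation
            return -v
        return v
    k = axis / s
    return v * c + np.cross(k, v) * s + k * np.dot(k, v) * (1.0 - c)


def elbow_swivel_series(
    shoulder: np.ndarray,
    elbow: np.ndarray,
    wrist: np.ndarray,
    eps_line: float | None = None,
    eps_axis: float = DEFAULT_EPS_AXIS,
    help_init: np.ndarray | None = None,
) -> SwivelSeries:
    """Elbow swivel angle with a moving help vector, defined at every frame.

    The help vector starts as the x-axis (projected orthogonal to the
    shoulder-wrist direction) and is parallel-transported frame to frame by
    the minimal rotation aligning successive shoulder-wrist directions,
    then re-orthogonalized and renormalized. Frames whose elbow lies closer
    than ``eps_line`` to the shoulder-wrist line are flagged
    ``straight_arm`` and hold the last valid angle (0 before the first
    valid frame). ``eps_line`` defaults to 1% of the arm length inferred
    from the first frame.
    """
    S = np.atleast_2d(np.asarray(shoulder, dtype=float))
    E = np.atleast_2d(np.asarray(elbow, dtype=float))
    W = np.atleast_2d(np.asarray(wrist, dtype=float))
    n = len(S)
    if eps_line is None:
        arm_len = np.linalg.norm(E[0] - S[0]) + np.linalg.norm(W[0] - E[0])
        eps_line = 0.01 * arm_len

    angle = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    helps = np.zeros((n, 3))
    reasons = [DegeneracyReason.NONE] * n

    r = np.array([1.0, 0.0, 0.0]) if help_init is None else np.asarray(
        help_init, dtype=float
    )
    u_prev = None
    last_valid = 0.0
    for k in range(n):
        sw = W[k] - S[k]
        sw_norm = np.linalg.norm(sw)
        u = sw / sw_norm
        if u_prev is not None:
            r = _rotate_minimal(r, u_prev, u)
        r = r - np.dot(r, u) * u
        r_norm = np.linalg.norm(r)
        if r_norm < 1e-9:  # help vector swallowed by the axis: re-seed
            fallback = np.array([0.0, 1.0, 0.0])
            r = fallback - np.dot(fallback, u) * u
            r_norm = np.linalg.norm(r)
        r = r / r_norm
        helps[k] = r
        u_prev = u

        # distance from elbow to the shoulder-wrist line
        se = E[k] - S[k]
        dist = np.linalg.norm(np.cross(se, u))
        if dist < eps_line:
            angle[k] = last_valid
            valid[k] = False
            reasons[k] = DegeneracyReason.STRAIGHT_ARM
            continue
        n_a = np.cross(se, sw)
        n_r = np.cross(u, r) * sw_norm
        cos_a = np.dot(n_a, n_r) / (np.linalg.norm(n_a) * np.linalg.norm(n_r))
        angle[k] = float(np.arccos(np.clip(cos_a, -1.0, 1.0)))
        valid[k] = True
        last_valid = angle[k]
    return SwivelSeries(angle=angle, valid=valid, help_vector=helps, degeneracy_reason=reasons)


def scale_swivel(angle: np.ndarray) -> np.ndarray:
    """Map the swivel angle from [0, pi] to the model input range [-1, 1]."""
    return 2.0 * np.asarray(angle, dtype=float) / np.pi - 1.0


class NoValidSwivelError(ValueError):
    """Swivel feature requested but no frame has a defined swivel angle."""


def assemble_features(
    eef_position_scaled: np.ndarray,
    eef_orientation: np.ndarray,
    swivel: SwivelSeries | None = None,
    include_swivel: bool = False,
) -> np.ndarray:
    """Stack the per-frame model input matrix.

    Columns are ``[px, py, pz, qw, qx, qy, qz]`` (7 features) and, when
    ``include_swivel``, the scaled swivel angle as an 8th column. Positions
    must already be session-scaled to [-1, 1].
    """
    pos = np.asarray(eef_position_scaled, dtype=float)
    quat = np.asarray(eef_orientation, dtype=float)
    if pos.shape[0] != quat.shape[0]:
        raise ValueError("position/orientation frame counts differ")
    cols = [pos, quat]
    if include_swivel:
        if swivel is None or not np.any(swivel.valid):
            raise NoValidSwivelError("no valid swivel frames for the 8th feature")
        cols.append(scale_swivel(swivel.angle)[:, None])
    return np.column_stack(cols)
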