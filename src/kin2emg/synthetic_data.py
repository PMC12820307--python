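"""Synthetic arm-movement/EMG study generator.

Emulates a motion-capture + surface-EMG acquisition: a right arm performs a
catalog of 23 upper-limb movement tasks (12 simple, 11 complex), each task
repeated many times per subject. Kinematics (joint positions, end-effector
position and orientation) are sampled at 60 Hz; raw EMG for 8 channels at
2222 Hz. Every trial carries the ground-truth activation envelope that
generated its EMG, so downstream estimators can be validated exactly.

The generative model is deliberately simple but respects the structure the
analysis assumes: joint trajectories are minimum-jerk interpolations through
task waypoints (bell-shaped speed profiles), muscle activation is a
rectified linear function of signed joint angular velocities plus a
gravity/posture term, low-pass filtered with an activation time constant,
and raw EMG is amplitude-modulated white noise riding on that envelope.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.spatial.transform import Rotation

JOINT_NAMES = (
    "shoulder_azimuth",
    "shoulder_elevation",
    "humeral_rotation",
    "elbow_flexion",
    "forearm_pronation",
    "wrist_flexion",
)
N_JOINTS = len(JOINT_NAMES)
N_CHANNELS = 8

#: EMG channel order (primary movers of the upper right arm).
CHANNEL_NAMES = (
    "deltoid_anterior",
    "deltoid_medial",
    "deltoid_posterior",
    "biceps_short_head",
    "triceps_lateral_head",
    "pronator_teres",
    "flexor_carpi_ulnaris",
    "extensor_carpi_ulnaris",
)

KIN_RATE = 60.0
EMG_RATE = 2222.0

#: Resting pose: arm hanging parallel to the body with a barely bent elbow
#: (a fully locked elbow would make the arm plane undefined at rest).
REST_POSE = np.array([0.0, 0.0, 0.0, 0.05, 0.0, 0.0])


class InvalidArgumentError(ValueError):
    """Raised when an operation receives arguments outside its contract."""


# ---------------------------------------------------------------------------
# Arm model and forward kinematics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArmModel:
    """Rigid two-segment arm (plus a short hand segment) rooted at the shoulder.

    In the zero pose all joint angles are zero and the arm hangs straight
    down: the wrist sits at ``shoulder - (L_u + L_f) * z``.
    """

    upper_arm_length: float = 0.30
    forearm_length: float = 0.25
    hand_length: float = 0.08
    shoulder_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    joint_names: tuple = JOINT_NAMES

    def __post_init__(self):
        if self.upper_arm_length <= 0 or self.forearm_length <= 0:
            raise InvalidArgumentError("segment lengths must be positive")


def forward_kinematics(arm: ArmModel, joint_angles: np.ndarray):
    """Map joint angles to shoulder/elbow/wrist positions and the hand frame.

    Parameters
    ----------
    arm : ArmModel
    joint_angles : array, shape (6,) or (N, 6)
        Angles in radians, ordered as :data:`JOINT_NAMES`.

    Returns
    -------
    shoulder, elbow, wrist, eef_position : arrays, shape (N, 3)
    eef_orientation : array, shape (N, 4)
        Unit quaternions (w, x, y, z) of the hand frame, sign-continuous
        along the trajectory.

    Notes
    -----
    Conventions (right arm, world frame: x forward/sagittal, z up):
    shoulder azimuth rotates about z, shoulder elevation raises the arm
    toward +x, humeral rotation spins the upper arm about its long axis,
    elbow flexion brings the forearm forward, pronation spins the forearm,
    wrist flexion tilts the hand. All poses are valid (no singularities in
    the map itself).
    """
    q = np.atleast_2d(np.asarray(joint_angles, dtype=float))
    if q.shape[1] != N_JOINTS:
        raise InvalidArgumentError(
            f"expected {N_JOINTS} joint angles, got {q.shape[1]}"
        )
    az, el, hum, flex, pron, wrist = (q[:, i] for i in range(N_JOINTS))

    r_upper = (
        Rotation.from_euler("z", az[:, None])
        * Rotation.from_euler("y", -el[:, None])
        * Rotation.from_euler("z", hum[:, None])
    )
    r_fore = (
        r_upper
        * Rotation.from_euler("y", -flex[:, None])
        * Rotation.from_euler("z", pron[:, None])
    )
    r_hand = r_fore * Rotation.from_euler("y", -wrist[:, None])

    shoulder = np.broadcast_to(arm.shoulder_origin, (len(q), 3)).copy()
    down_u = np.array([0.0, 0.0, -arm.upper_arm_length])
    down_f = np.array([0.0, 0.0, -arm.forearm_length])
    down_h = np.array([0.0, 0.0, -arm.hand_length])
    ones = np.ones((len(q), 1))
    elbow = shoulder + r_upper.apply(ones * down_u)
    wrist_p = elbow + r_fore.apply(ones * down_f)
    eef = wrist_p + r_hand.apply(ones * down_h)

    quat_xyzw = np.atleast_2d(r_hand.as_quat())
    quat = np.column_stack([quat_xyzw[:, 3], quat_xyzw[:, :3]])
    quat = _fix_quaternion_hemisphere(quat)

    if np.ndim(joint_angles) == 1:
        return shoulder[0], elbow[0], wrist_p[0], eef[0], quat[0]
    return shoulder, elbow, wrist_p, eef, quat


def _fix_quaternion_hemisphere(quat: np.ndarray) -> np.ndarray:
    """Flip quaternion signs so consecutive frames never jump hemispheres."""
    out = quat.copy()
    for k in range(1, len(out)):
        if np.dot(out[k], out[k - 1]) < 0:
            out[k] = -out[k]
    return out


# ---------------------------------------------------------------------------
# Minimum-jerk trajectories
# ---------------------------------------------------------------------------


def min_jerk_profile(start, end, duration: float, rate: float) -> np.ndarray:
    """Sample a minimum-jerk point-to-point trajectory.

    Position follows ``x(tau) = x0 + (x1 - x0)(10 tau^3 - 15 tau^4 + 6 tau^5)``
    with ``tau = t / duration``; velocity and acceleration vanish at both
    ends, and the speed profile is the classic bell shape with peak
    ``1.875 * |x1 - x0| / duration`` at the midpoint.

    ``start`` and ``end`` may be scalars or vectors; the returned array has
    one row per sample including both endpoints.
    """
    if duration <= 0 or rate <= 0:
        raise InvalidArgumentError("duration and rate must be positive")
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    n = int(round(duration * rate)) + 1
    tau = np.linspace(0.0, 1.0, n)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    return start + np.multiply.outer(s, end - start)


def _min_jerk_s(tau: np.ndarray) -> np.ndarray:
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


# ---------------------------------------------------------------------------
# Task catalog
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaskSpec:
    """One movement task: named joint-space waypoints traversed in order.

    The first and last waypoint equal the resting pose, and the instructed
    duration fits the acquisition's 7.5 s instruction window.
    """

    name: str
    category: str  # "simple" | "complex"
    joint_waypoints: tuple  # tuple of length-6 arrays (radians)
    duration: float  # seconds for the waypoint path, excluding rest padding
    out_and_back: bool = True  # False marks one-way diagnostic strokes

    def __post_init__(self):
        if self.category not in ("simple", "complex"):
            raise InvalidArgumentError(f"bad category {self.category!r}")
        if self.duration > 7.5:
            raise InvalidArgumentError("duration exceeds the 7.5 s instruction window")
        wp = [np.asarray(w, dtype=float) for w in self.joint_waypoints]
        if len(wp) < 2:
            raise InvalidArgumentError("need at least two waypoints")
        if self.out_and_back and not (
            np.allclose(wp[0], REST_POSE) and np.allclose(wp[-1], REST_POSE)
        ):
            raise InvalidArgumentError("tasks must start and end at the resting pose")


def _pose(**kwargs) -> np.ndarray:
    p = REST_POSE.copy()
    idx = {n: i for i, n in enumerate(JOINT_NAMES)}
    short = {"az": 0, "el": 1, "hum": 2, "elbow": 3, "pron": 4, "wrist": 5}
    for k, v in kwargs.items():
        p[short.get(k, idx.get(k))] = v
    return p


def default_task_catalog() -> list:
    """The 23-task study catalog: 12 simple and 11 complex movements.

    Waypoint amplitudes approximate the described executions (e.g. shoulder
    flexion raised to 90 degrees in the sagittal plane); exact joint paths
    are a modelling choice.
    """
    R = REST_POSE
    hp = np.pi / 2
    simple = [
        TaskSpec("shoulder flexion (90)", "simple", (R, _pose(el=hp), R), 3.5),
        TaskSpec(
            "shoulder flexion (mix)",
            "simple",
            (R, _pose(el=1.3), _pose(el=0.5), _pose(el=1.55), R),
            6.0,
        ),
        TaskSpec("shoulder extension", "simple", (R, _pose(el=-0.52), R), 3.0),
        TaskSpec(
            "shoulder abduction (90)", "simple", (R, _pose(az=-hp, el=hp), R), 3.5
        ),
        TaskSpec(
            "shoulder abduction (mix)",
            "simple",
            (R, _pose(az=-hp, el=1.3), _pose(az=-hp, el=0.6), _pose(az=-hp, el=1.5), R),
            6.0,
        ),
        TaskSpec("elbow flexion", "simple", (R, _pose(elbow=2.1), R), 3.0),
        TaskSpec(
            "elbow flexion (mix)",
            "simple",
            (R, _pose(elbow=2.2), _pose(elbow=1.0), _pose(elbow=1.9), R),
            5.5,
        ),
        TaskSpec(
            "elbow flexion with a supinated forearm",
            "simple",
            (R, _pose(pron=-1.3), _pose(pron=-1.3, elbow=2.1), _pose(pron=-1.3), R),
            5.5,
        ),
        TaskSpec("wrist flexion", "simple", (R, _pose(wrist=1.0), R), 3.0),
        TaskSpec("wrist extension", "simple", (R, _pose(wrist=-1.0), R), 3.0),
        TaskSpec("wrist pronation", "simple", (R, _pose(pron=1.4), R), 3.0),
        TaskSpec(
            "shoulder abduction & flexion",
            "simple",
            (R, _pose(az=-hp, el=1.4), R, _pose(el=1.4), R),
            6.5,
        ),
    ]
    complex_ = [
        TaskSpec(
            "shoulder abduction with simultaneous elbow flexion",
            "complex",
            (R, _pose(az=-hp, el=1.4, elbow=1.8), R),
            4.0,
        ),
        TaskSpec(
            "shoulder flexion with simultaneous elbow flexion",
            "complex",
            (R, _pose(el=1.4, elbow=1.8), R),
            4.0,
        ),
        TaskSpec(
            "shoulder abduction with simultaneous wrist extension",
            "complex",
            (R, _pose(az=-hp, el=1.4, wrist=-0.9), R),
            4.0,
        ),
        TaskSpec(
            "arm roll",
            "complex",
            (
                R,
                _pose(el=0.9, elbow=1.6),
                _pose(el=0.9, elbow=1.6, hum=0.8, pron=1.0),
                _pose(el=0.9, elbow=1.6, hum=-0.8, pron=-1.0),
                _pose(el=0.9, elbow=1.6, hum=0.8, pron=1.0),
                R,
            ),
            6.0,
        ),
        TaskSpec(
            "breaststroke",
            "complex",
            (
                R,
                _pose(el=1.3, elbow=1.9),
                _pose(el=1.5, elbow=0.2),
                _pose(az=-1.2, el=1.2, elbow=0.3),
                _pose(az=-0.4, el=0.6, elbow=1.5),
                R,
            ),
            6.5,
        ),
        TaskSpec(
            "relay handover",
            "complex",
            (
                R,
                _pose(el=-0.5, elbow=0.4, pron=1.2),
                _pose(el=-0.75, elbow=0.5, pron=1.4, wrist=0.4),
                R,
            ),
            5.0,
        ),
        TaskSpec(
            "reading a watch",
            "complex",
            (
                R,
                _pose(el=0.5, elbow=2.3, pron=0.9),
                _pose(el=0.6, elbow=2.5, pron=1.2, hum=0.4),
                R,
            ),
            5.0,
        ),
        TaskSpec(
            "diagonal reach",
            "complex",
            (
                R,
                _pose(az=0.9, el=1.1, elbow=0.6),
                _pose(az=1.1, el=1.5, elbow=0.2),
                R,
            ),
            5.0,
        ),
        TaskSpec(
            "waving gestures",
            "complex",
            (
                R,
                _pose(el=0.9, elbow=1.8),
                _pose(el=0.9, elbow=1.8, wrist=0.6),
                _pose(el=0.9, elbow=1.8, wrist=-0.6),
                _pose(el=0.9, elbow=1.8, wrist=0.6),
                _pose(el=0.9, elbow=1.8),
                R,
            ),
            6.0,
        ),
        TaskSpec(
            "drawing a circle",
            "complex",
            (
                R,
                _pose(az=0.3, el=1.1, elbow=0.5),
                _pose(az=0.0, el=1.4, elbow=0.4),
                _pose(az=-0.5, el=1.1, elbow=0.5),
                _pose(az=0.0, el=0.8, elbow=0.7),
                _pose(az=0.3, el=1.1, elbow=0.5),
                R,
            ),
            6.5,
        ),
        TaskSpec(
            "drawing a line",
            "complex",
            (
                R,
                _pose(az=0.4, el=1.0, elbow=0.6),
                _pose(az=-0.6, el=1.0, elbow=0.4),
                R,
            ),
            5.0,
        ),
    ]
    return simple + complex_


#: Tasks that are missing for one subject in the emulated acquisition
#: (electrode loosening / mis-execution): 8 of the 23 tasks, leaving 15
#: available for every subject.
MISSING_TASKS = (
    "elbow flexion with a supinated forearm",
    "wrist flexion",
    "shoulder abduction & flexion",
    "shoulder flexion with simultaneous elbow flexion",
    "arm roll",
    "diagonal reach",
    "drawing a circle",
    "drawing a line",
)


def default_availability(n_subjects: int = 5, emulate_missing: bool = True) -> dict:
    """Per-subject task availability grid.

    When ``emulate_missing`` each task in :data:`MISSING_TASKS` is flagged
    unavailable for one subject (round-robin), mirroring the study's
    missing cells; the set-intersection over subjects then has 15 tasks.
    """
    tasks = [t.name for t in default_task_catalog()]
    avail = {s: {t: True for t in tasks} for s in range(1, n_subjects + 1)}
    if emulate_missing:
        for k, task in enumerate(MISSING_TASKS):
            subject = (k % n_subjects) + 1
            avail[subject][task] = False
    return avail


def common_tasks(availability: dict) -> list:
    """Tasks available for every subject, in catalog order."""
    subjects = list(availability)
    first = availability[subjects[0]]
    return [
        t for t in first if all(availability[s].get(t, False) for s in subjects)
    ]


# ---------------------------------------------------------------------------
# Ground-truth EMG model
# ---------------------------------------------------------------------------


@dataclass
class GroundTruthEMGModel:
    """Generative kinematics-to-activation mapping with known structure.

    Per channel i, the neural drive is a rectified linear mixture of signed
    joint angular velocities plus a gravity/posture term::

        u_i(t) = sum_j [w+_ij max(0, w_j(t)) + w-_ij max(0, -w_j(t))]
                 + sum_k g_ik p_k(theta(t))

    low-pass filtered with time constant ``tau_act`` (first-order muscle
    activation dynamics) and divided by a per-channel calibration ``scale``
    so session envelopes stay in [0, 1]. Raw EMG is the envelope times
    unit-variance white noise plus a baseline noise floor.
    """

    w_pos: np.ndarray  # (8, 6) gains on positive joint velocity
    w_neg: np.ndarray  # (8, 6) gains on negative joint velocity
    posture_gain: np.ndarray  # (8, 2) gains on gravity features
    tau_act: float = 0.06  # s
    modulation_noise_sd: float = 1.0  # unit-variance amplitude modulation
    baseline_noise_sd: float = 0.01
    scale: np.ndarray = field(default_factory=lambda: np.ones(N_CHANNELS))

    def __post_init__(self):
        if self.tau_act <= 0:
            raise InvalidArgumentError("activation time constant must be positive")

    def posture_features(self, joint_angles: np.ndarray) -> np.ndarray:
        """Gravity loading features: shoulder elevation and elbow flexion moments."""
        el = joint_angles[:, 1]
        elbow = joint_angles[:, 3]
        f1 = np.abs(np.sin(el))
        f2 = np.maximum(0.0, np.sin(elbow))
        return np.column_stack([f1, f2])

    def envelope(self, joint_angles: np.ndarray, dt: float) -> np.ndarray:
        """Ground-truth activation envelope, one row per kinematic frame."""
        omega = np.gradient(joint_angles, dt, axis=0)
        drive = (
            np.maximum(omega, 0.0) @ self.w_pos.T
            + np.maximum(-omega, 0.0) @ self.w_neg.T
            + self.posture_features(joint_angles) @ self.posture_gain.T
        )
        drive = np.maximum(drive, 0.0)
        act = np.empty_like(drive)
        # first-order discrete low-pass; alpha capped at 1 (tau below the
        # frame interval degenerates to no filtering, not instability)
        alpha = min(1.0, dt / self.tau_act)
        acc = drive[0]
        act[0] = acc
        for k in range(1, len(drive)):
            acc = acc + alpha * (drive[k] - acc)
            act[k] = acc
        return np.clip(act / self.scale, 0.0, 1.0)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for a in (self.w_pos, self.w_neg, self.posture_gain, self.scale):
            h.update(np.ascontiguousarray(a, dtype=np.float64).tobytes())
        h.update(np.float64([self.tau_act, self.baseline_noise_sd]).tobytes())
        return h.hexdigest()[:16]


def base_emg_model(baseline_noise_sd: float = 0.01) -> GroundTruthEMGModel:
    """Population-level gain structure mapping joints to the 8 channels.

    Each channel is driven primarily by the joint motions its muscle
    actuates (e.g. anterior deltoid by shoulder elevation, biceps by elbow
    flexion and supination), with small cross-talk everywhere.
    """
    wp = np.full((N_CHANNELS, N_JOINTS), 0.05)
    wn = np.full((N_CHANNELS, N_JOINTS), 0.05)
    J = {n: i for i, n in enumerate(JOINT_NAMES)}
    # deltoid anterior: shoulder flexion (raising)
    wp[0, J["shoulder_elevation"]] = 1.0
    # deltoid medial: abduction (elevation with negative azimuth drift)
    wp[1, J["shoulder_elevation"]] = 0.8
    wn[1, J["shoulder_azimuth"]] = 0.6
    # deltoid posterior: extension / lowering
    wn[2, J["shoulder_elevation"]] = 0.9
    wp[2, J["shoulder_azimuth"]] = 0.3
    # biceps: elbow flexion + supination
    wp[3, J["elbow_flexion"]] = 1.0
    wn[3, J["forearm_pronation"]] = 0.3
    # triceps: elbow extension
    wn[4, J["elbow_flexion"]] = 1.0
    wn[4, J["shoulder_elevation"]] = 0.2
    # pronator teres: pronation + weak elbow flexion
    wp[5, J["forearm_pronation"]] = 1.0
    wp[5, J["elbow_flexion"]] = 0.2
    # flexor carpi ulnaris: wrist flexion
    wp[6, J["wrist_flexion"]] = 1.0
    # extensor carpi ulnaris: wrist extension + pronation stabilization
    wn[7, J["wrist_flexion"]] = 1.0
    wp[7, J["forearm_pronation"]] = 0.2
    gp = np.zeros((N_CHANNELS, 2))
    gp[0, 0], gp[1, 0], gp[2, 0] = 0.30, 0.35, 0.12
    gp[3, 1], gp[4, 1] = 0.25, 0.05
    return GroundTruthEMGModel(
        w_pos=wp, w_neg=wn, posture_gain=gp, baseline_noise_sd=baseline_noise_sd
    )


def subject_emg_model(
    base: GroundTruthEMGModel, rng: np.random.Generator, gain_jitter_sd: float = 0.15
) -> GroundTruthEMGModel:
    """Subject-specific model: all gains jittered by a lognormal factor."""

    def jit(a):
        return a * np.exp(rng.normal(0.0, gain_jitter_sd, size=a.shape))

    return replace(
        base,
        w_pos=jit(base.w_pos),
        w_neg=jit(base.w_neg),
        posture_gain=jit(base.posture_gain),
        scale=base.scale.copy(),
    )


# ---------------------------------------------------------------------------
# Trial synthesis
# ---------------------------------------------------------------------------


@dataclass
class Trial:
    """One repetition of one movement: synchronized kinematics and raw EMG."""

    subject: int
    task: str
    repetition: int
    kin_timestamps: np.ndarray  # (N,) s, 60 Hz
    joint_angles: np.ndarray  # (N, 6) rad
    shoulder: np.ndarray  # (N, 3) m
    elbow: np.ndarray
    wrist: np.ndarray
    eef_position: np.ndarray
    eef_orientation: np.ndarray  # (N, 4) unit quaternion (w, x, y, z)
    emg_timestamps: np.ndarray  # (M,) s, 2222 Hz
    raw_emg: np.ndarray  # (M, 8)
    gt_envelope: np.ndarray | None = None  # (N, 8) in [0, 1], synthetic only


def _leg_durations(waypoints, total: float) -> np.ndarray:
    """Allocate the task duration across waypoint legs by joint excursion."""
    deltas = np.array(
        [
            np.max(np.abs(np.asarray(b) - np.asarray(a)))
            for a, b in zip(waypoints[:-1], waypoints[1:])
        ]
    )
    w = np.maximum(deltas, 1e-3)
    return total * w / w.sum()


def joint_trajectory(
    task: TaskSpec,
    rate: float = KIN_RATE,
    rest_pad: float = 0.5,
    amplitude_scale: float = 1.0,
    duration_scale: float = 1.0,
) -> tuple:
    """Piecewise minimum-jerk joint trajectory through the task waypoints.

    Returns ``(timestamps, joint_angles)`` on a uniform grid at ``rate``,
    with ``rest_pad`` seconds of rest at both ends.
    """
    wps = [
        REST_POSE + amplitude_scale * (np.asarray(w, dtype=float) - REST_POSE)
        for w in task.joint_waypoints
    ]
    legs = _leg_durations(task.joint_waypoints, task.duration * duration_scale)
    starts = rest_pad + np.concatenate([[0.0], np.cumsum(legs)])
    total = starts[-1] + rest_pad
    n = int(round(total * rate)) + 1
    t = np.arange(n) / rate
    q = np.empty((n, N_JOINTS))
    q[:] = wps[0]
    for i, (a, b) in enumerate(zip(wps[:-1], wps[1:])):
        lo, hi = starts[i], starts[i + 1]
        sel = (t >= lo) & (t < hi)
        tau = (t[sel] - lo) / (hi - lo)
        q[sel] = a + np.multiply.outer(_min_jerk_s(tau), b - a)
    q[t >= starts[-1]] = wps[-1]
    return t, q


def synthesize_trial(
    arm: ArmModel,
    task: TaskSpec,
    gt: GroundTruthEMGModel,
    seed,
    subject: int = 0,
    repetition: int = 0,
    rate_kin: float = KIN_RATE,
    rate_emg: float = EMG_RATE,
    rest_pad: float = 0.5,
    amplitude_jitter_sd: float = 0.05,
    duration_jitter_sd: float = 0.05,
    joint_noise_sd: float = np.deg2rad(0.5),
) -> Trial:
    """Simulate one repetition: kinematics at 60 Hz, raw EMG at 2222 Hz.

    ``seed`` is mandatory (int or :class:`numpy.random.SeedSequence`);
    regenerating with the same seed reproduces every array bit-identically.
    Per-repetition jitter multiplies waypoint amplitudes and the task
    duration by independent N(1, sd^2) factors and adds smooth joint noise.
    """
    if seed is None:
        raise InvalidArgumentError("synthesize_trial requires an explicit seed")
    rng = np.random.default_rng(seed)

    amp = 1.0 + amplitude_jitter_sd * rng.standard_normal()
    dur = max(0.3, 1.0 + duration_jitter_sd * rng.standard_normal())
    t_kin, q = joint_trajectory(
        task, rate_kin, rest_pad, amplitude_scale=amp, duration_scale=dur
    )
    if joint_noise_sd > 0:
        # smooth execution noise: ~100 ms correlation time keeps the induced
        # envelope fluctuations slower than the 200 ms RMS analysis window
        noise = rng.standard_normal(q.shape)
        noise = gaussian_filter1d(noise, sigma=0.1 * rate_kin, axis=0, mode="reflect")
        sd = noise.std(axis=0)
        sd[sd == 0] = 1.0
        q = q + joint_noise_sd * noise / sd

    shoulder, elbow, wrist, eef, quat = forward_kinematics(arm, q)
    envelope = gt.envelope(q, 1.0 / rate_kin)

    n_emg = int(round(t_kin[-1] * rate_emg)) + 1
    t_emg = np.arange(n_emg) / rate_emg
    amp_mod = np.empty((n_emg, N_CHANNELS))
    for c in range(N_CHANNELS):
        amp_mod[:, c] = np.interp(t_emg, t_kin, envelope[:, c])
    raw = amp_mod * rng.standard_normal((n_emg, N_CHANNELS))
    if gt.baseline_noise_sd > 0:
        raw += gt.baseline_noise_sd * rng.standard_normal((n_emg, N_CHANNELS))

    return Trial(
        subject=subject,
        task=task.name,
        repetition=repetition,
        kin_timestamps=t_kin,
        joint_angles=q,
        shoulder=shoulder,
        elbow=elbow,
        wrist=wrist,
        eef_position=eef,
        eef_orientation=quat,
        emg_timestamps=t_emg,
        raw_emg=raw.astype(np.float32),
        gt_envelope=envelope,
    )


# ---------------------------------------------------------------------------
# Study generation
# ---------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """Conditions of the emulated acquisition.

    Defaults mirror the full study (5 subjects x 23 tasks x 18 repetitions);
    tests and the desk-scale experiment grid pass smaller values.
    """

    n_subjects: int = 5
    n_reps: int = 18
    tasks: list = field(default_factory=default_task_catalog)
    emulate_missing: bool = False
    rest_pad: float = 0.5
    baseline_noise_sd: float = 0.01
    gain_jitter_sd: float = 0.15
    amplitude_jitter_sd: float = 0.05
    duration_jitter_sd: float = 0.05
    joint_noise_sd: float = float(np.deg2rad(0.5))
    rate_kin: float = KIN_RATE
    rate_emg: float = EMG_RATE
    arm: ArmModel = field(default_factory=ArmModel)


@dataclass
class SessionManifest:
    """Study index: subjects, tasks, availability, and (optionally) trials."""

    subject_ids: list
    tasks: dict  # name -> TaskSpec
    availability: dict  # subject -> {task name -> bool}
    n_reps: int
    seed: int | None = None
    trials: dict | None = None  # (subject, task name) -> list[Trial]
    gt_models: dict | None = None  # subject -> GroundTruthEMGModel
    gt_hash: dict | None = None

    @property
    def categories(self) -> dict:
        return {name: t.category for name, t in self.tasks.items()}

    def available_tasks(self, subject) -> list:
        return [t for t, ok in self.availability[subject].items() if ok]

    def rep_count(self, subject, task) -> int:
        if self.trials is not None and (subject, task) in self.trials:
            return len(self.trials[(subject, task)])
        return self.n_reps if self.availability[subject].get(task, False) else 0


def build_manifest(config: StudyConfig, seed: int | None = None) -> SessionManifest:
    """Structural manifest (catalog + availability) without synthesizing trials."""
    avail = {}
    full = default_availability(config.n_subjects, emulate_missing=True)
    names = [t.name for t in config.tasks]
    for s in range(1, config.n_subjects + 1):
        if config.emulate_missing:
            avail[s] = {n: full.get(s, {}).get(n, True) for n in names}
        else:
            avail[s] = {n: True for n in names}
    return SessionManifest(
        subject_ids=list(range(1, config.n_subjects + 1)),
        tasks={t.name: t for t in config.tasks},
        availability=avail,
        n_reps=config.n_reps,
        seed=seed,
    )


def _calibrate_scale(
    arm: ArmModel, tasks, gt: GroundTruthEMGModel, rate: float, rest_pad: float
) -> np.ndarray:
    """Per-channel divisor: 1.1 x the nominal session envelope maximum."""
    peak = np.full(N_CHANNELS, 1e-12)
    for task in tasks:
        _, q = joint_trajectory(task, rate, rest_pad)
        env = replace(gt, scale=np.ones(N_CHANNELS)).envelope(q, 1.0 / rate)
        peak = np.maximum(peak, env.max(axis=0))
    return 1.1 * peak


def generate_study(
    config: StudyConfig | None = None, seed: int = 0, out_dir=None
) -> SessionManifest:
    """Generate the full synthetic study, deterministically from ``seed``.

    Every subject gets a jittered copy of the population gain structure
    (calibrated so session envelopes stay within [0, 1]); every available
    task gets ``n_reps`` jittered repetitions. With ``out_dir`` the trials
    and a ``manifest.json`` are also written as CSV files.
    """
    config = config or StudyConfig()
    manifest = build_manifest(config, seed=seed)
    base = base_emg_model(config.baseline_noise_sd)

    manifest.trials = {}
    manifest.gt_models = {}
    manifest.gt_hash = {}
    for s in manifest.subject_ids:
        subj_ss = np.random.SeedSequence(entropy=seed, spawn_key=(s,))
        gt = subject_emg_model(
            base, np.random.default_rng(subj_ss), config.gain_jitter_sd
        )
        gt.scale = _calibrate_scale(
            config.arm, config.tasks, gt, config.rate_kin, config.rest_pad
        )
        manifest.gt_models[s] = gt
        manifest.gt_hash[s] = gt.content_hash()
        for task in config.tasks:
            if not manifest.availability[s][task.name]:
                continue
            trials = []
            for rep in range(config.n_reps):
                trial_ss = np.random.SeedSequence(
                    entropy=seed, spawn_key=(s, config.tasks.index(task), rep)
                )
                trials.append(
                    synthesize_trial(
                        config.arm,
                        task,
                        gt,
                        trial_ss,
                        subject=s,
                        repetition=rep,
                        rate_kin=config.rate_kin,
                        rate_emg=config.rate_emg,
                        rest_pad=config.rest_pad,
                        amplitude_jitter_sd=config.amplitude_jitter_sd,
                        duration_jitter_sd=config.duration_jitter_sd,
                        joint_noise_sd=config.joint_noise_sd,
                    )
                )
            manifest.trials[(s, task.name)] = trials
    if out_dir is not None:
        write_study(manifest, out_dir)
    return manifest


# ---------------------------------------------------------------------------
# Disk format
# ---------------------------------------------------------------------------

KIN_HEADER = "t,Sx,Sy,Sz,Ex,Ey,Ez,Wx,Wy,Wz,px,py,pz,qw,qx,qy,qz"
EMG_HEADER = "t," + ",".join(f"ch{i}" for i in range(1, 9))


def write_study(manifest: SessionManifest, out_dir) -> None:
    """Write per-trial kinematics/EMG CSVs and a ``manifest.json`` index."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index = {
        "seed": manifest.seed,
        "n_reps": manifest.n_reps,
        "subjects": manifest.subject_ids,
        "categories": manifest.categories,
        "availability": {
            str(s): manifest.availability[s] for s in manifest.subject_ids
        },
        "gt_hash": {str(s): h for s, h in (manifest.gt_hash or {}).items()},
        "trials": {},
    }
    for (s, task), trials in (manifest.trials or {}).items():
        slug = task.replace(" ", "_").replace("&", "and")
        paths = []
        for trial in trials:
            stem = f"s{s:02d}_{slug}_r{trial.repetition:02d}"
            kin = np.column_stack(
                [
                    trial.kin_timestamps,
                    trial.shoulder,
                    trial.elbow,
                    trial.wrist,
                    trial.eef_position,
                    trial.eef_orientation,
                ]
            )
            np.savetxt(
                out / f"{stem}_kin.csv",
                kin,
                delimiter=",",
                header=KIN_HEADER,
                comments="",
                fmt="%.9g",
            )
            emg = np.column_stack([trial.emg_timestamps, trial.raw_emg])
            np.savetxt(
                out / f"{stem}_emg.csv",
                emg,
                delimiter=",",
                header=EMG_HEADER,
                comments="",
                fmt="%.7g",
            )
            paths.append(stem)
        index["trials"][f"{s}|{task}"] = paths
    with open(out / "manifest.json", "w") as fh:
        json.dump(index, fh, indent=1, sort_keys=True)


def load_trial_csvs(directory, stem: str) -> tuple:
    """Read back one trial's kinematics and EMG CSVs (arrays, not a Trial)."""
    kin = np.loadtxt(Path(directory) / f"{stem}_kin.csv", delimiter=",", skiprows=1)
    emg = np.loadtxt(Path(directory) / f"{stem}_emg.csv", delimiter=",", skiprows=1)
    return kin, emg
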