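"""Synthetic motion and goniometry: the hardware-free test bed.

Everything the pipeline consumes can be generated here: noisy skeleton
sequences from a rigid forward-kinematic arm model, whole-degree goniometer
readings with observer bias, and the two validation protocols (static
abduction ladder for method agreement; repeated 90-degree flexion for
test-retest repeatability).

Conventions (invented, fixed, documented):

* the subject stands 2 m from the sensor facing it; hip_center sits at
  ``(0, 0, 2)`` in the camera frame;
* a commanded angle of 0 deg means the arm hangs straight down; the angle
  rotates the whole (straight) arm in the requested anatomical plane --
  coronal: sideways away from the trunk (abduction, toward +x for the right
  side as seen by the camera, -x for the left); sagittal: forward toward
  the sensor (flexion); axial: horizontally from the abducted direction
  toward forward, i.e. the arm stays at 90 deg elevation;
* segment lengths default to standard anthropometric fractions of the
  stated cohort stature (1.69 m): upper arm 0.186 H, forearm 0.146 H,
  hand 0.108 H, trunk 0.30 H, half shoulder width 0.129 H;
* sensor noise is isotropic Gaussian per joint coordinate with sd at the
  depth-camera error scale (default 0.02 m, within the reported
  14.1-34.8 mm range), plus sporadic isolated outliers: with probability
  ``outlier_rate`` per joint per frame the sample is displaced by
  ``outlier_scale * position_sd`` in a uniformly random direction;
* the manual goniometer reads truth plus observer bias plus Gaussian
  observer noise, quantised to whole degrees.

Identical configurations and seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .agreement import PairedMeasurements
from .kinematics import angle_series
from .preprocess import OutlierPolicy, SmoothingConfig, preprocess_sequence
from .skeleton import AnatomicalPlane, SkeletonSequence, resolve_plane

__all__ = [
    "ArmModel",
    "NoiseConfig",
    "GoniometerModel",
    "constant",
    "ramp",
    "simulate_movement",
    "static_pose",
    "protocol1_static",
    "protocol2_sessions",
    "COHORT_HEIGHT_M",
    "COHORT_HEIGHT_SD_M",
]

#: Study cohort stature (mean +/- sd, meters) used to scale arm models.
COHORT_HEIGHT_M = 1.69
COHORT_HEIGHT_SD_M = 0.11


@dataclass(frozen=True)
class ArmModel:
    """Rigid segment lengths (meters) of the simulated subject."""

    trunk: float = 0.30 * COHORT_HEIGHT_M
    shoulder_offset: float = 0.129 * COHORT_HEIGHT_M
    upper_arm: float = 0.186 * COHORT_HEIGHT_M
    forearm: float = 0.146 * COHORT_HEIGHT_M
    hand: float = 0.108 * COHORT_HEIGHT_M
    head_offset: float = 0.13 * COHORT_HEIGHT_M

    def __post_init__(self) -> None:
        for name in ("trunk", "shoulder_offset", "upper_arm", "forearm", "hand", "head_offset"):
            if not getattr(self, name) > 0:
                raise ValueError(f"segment length {name} must be positive")

    @classmethod
    def from_height(cls, height_m: float) -> "ArmModel":
        """Scale all segment lengths to a subject stature."""
        if not height_m > 0:
            raise ValueError(f"height must be positive, got {height_m}")
        s = height_m / COHORT_HEIGHT_M
        base = cls()
        return cls(
            trunk=base.trunk * s,
            shoulder_offset=base.shoulder_offset * s,
            upper_arm=base.upper_arm * s,
            forearm=base.forearm * s,
            hand=base.hand * s,
            head_offset=base.head_offset * s,
        )


@dataclass(frozen=True)
class NoiseConfig:
    """Sensor noise model: Gaussian jitter plus sporadic large outliers."""

    position_sd: float = 0.02
    outlier_rate: float = 0.0
    outlier_scale: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.position_sd < 0:
            raise ValueError("position_sd must be >= 0")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be in [0, 1]")
        if self.outlier_scale < 0:
            raise ValueError("outlier_scale must be >= 0")


@dataclass(frozen=True)
class GoniometerModel:
    """Manual goniometer: truth + observer bias + noise, whole-degree dial.

    ``quantization=0`` disables rounding (an idealised continuous reader).
    """

    observer_bias: float = 0.0
    observer_sd: float = 1.5
    quantization: float = 1.0

    def __post_init__(self) -> None:
        if self.observer_sd < 0 or self.quantization < 0:
            raise ValueError("observer_sd and quantization must be >= 0")

    def read(self, true_angle: float, rng: np.random.Generator) -> float:
        r = true_angle + self.observer_bias
        if self.observer_sd > 0:
            r += rng.normal(0.0, self.observer_sd)
        if self.quantization > 0:
            r = round(r / self.quantization) * self.quantization
        return float(r)


# ---------------------------------------------------------------------------
# movement profiles


def constant(angle_deg: float) -> Callable[[np.ndarray], np.ndarray]:
    """Static hold at ``angle_deg``."""
    return lambda t: np.full(np.shape(t), float(angle_deg))


def ramp(start_deg: float, stop_deg: float, duration_s: float) -> Callable[[np.ndarray], np.ndarray]:
    """Linear excursion from start to stop over ``duration_s`` seconds."""
    if not duration_s > 0:
        raise ValueError("duration_s must be positive")
    return lambda t: start_deg + (stop_deg - start_deg) * np.clip(
        np.asarray(t, float) / duration_s, 0.0, 1.0
    )


# ---------------------------------------------------------------------------
# forward kinematics


def _plane_basis(plane: AnatomicalPlane, side: str) -> tuple[np.ndarray, np.ndarray]:
    """(zero-angle direction, positive-rotation direction) for a movement plane."""
    sx = 1.0 if side == "right" else -1.0
    down = np.array([0.0, -1.0, 0.0])
    lateral = np.array([sx, 0.0, 0.0])
    forward = np.array([0.0, 0.0, -1.0])  # toward the sensor
    if plane.name == "coronal":
        return down, lateral
    if plane.name == "sagittal":
        return down, forward
    if plane.name == "axial":
        return lateral, forward
    raise ValueError(f"unsupported movement plane {plane.name!r}")


_MINIMAL_JOINTS = ("hip_center", "shoulder_center")


def simulate_movement(
    profile: Callable[[np.ndarray], np.ndarray],
    plane: "str | AnatomicalPlane",
    arm: "ArmModel | None" = None,
    noise: "NoiseConfig | None" = None,
    fps: float = 30.0,
    duration: float = 1.0,
    side: str = "right",
    base: Sequence[float] = (0.0, 0.0, 2.0),
    joints: str = "upper",
    rng: "np.random.Generator | None" = None,
) -> SkeletonSequence:
    """Rigid forward-kinematic arm movement sampled at ``fps``.

    ``profile`` maps time (seconds, array) to the commanded angle (degrees);
    the straight arm (shoulder to hand) rotates in ``plane`` about the
    shoulder pivot.  ``joints='upper'`` emits the 12 upper-body joints (both
    sides; the contralateral arm hangs at 0 deg); ``joints='minimal'`` emits
    only the moving side's chain, for fast batch simulation.  Sensor noise
    per :class:`NoiseConfig`; passing ``rng`` overrides ``noise.seed``.
    """
    arm = arm or ArmModel()
    noise = noise or NoiseConfig(position_sd=0.0)
    if not fps > 0 or not duration > 0:
        raise ValueError("fps and duration must be positive")
    p = resolve_plane(plane)
    if p is None:
        raise ValueError("simulate_movement needs a movement plane, not '3d'")
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    n = max(int(round(fps * duration)), 1)
    t = np.arange(n, dtype=float) / fps
    theta = np.broadcast_to(np.asarray(profile(t), dtype=float), t.shape)
    th = np.radians(theta)

    base = np.asarray(base, dtype=float)
    hip_center = base
    shoulder_center = base + np.array([0.0, arm.trunk, 0.0])
    head = shoulder_center + np.array([0.0, arm.head_offset, 0.0])
    spine = base + np.array([0.0, 0.5 * arm.trunk, 0.0])

    e0, e1 = _plane_basis(p, side)
    d = np.cos(th)[:, None] * e0 + np.sin(th)[:, None] * e1  # (n, 3) unit

    def chain(shoulder: np.ndarray, direction: np.ndarray) -> dict[str, np.ndarray]:
        elbow = shoulder + arm.upper_arm * direction
        wrist = elbow + arm.forearm * direction
        hand = wrist + arm.hand * direction
        return {"elbow": elbow, "wrist": wrist, "hand": hand}

    positions: dict[str, np.ndarray] = {}

    def add_static(label: str, point: np.ndarray) -> None:
        positions[label] = np.tile(point, (n, 1))

    add_static("hip_center", hip_center)
    add_static("shoulder_center", shoulder_center)
    sx = 1.0 if side == "right" else -1.0
    shoulder = shoulder_center + np.array([sx * arm.shoulder_offset, 0.0, 0.0])
    add_static(f"shoulder_{side}", shoulder)
    for joint, pos in chain(shoulder, d).items():
        positions[f"{joint}_{side}"] = pos

    if joints == "upper":
        add_static("spine", spine)
        add_static("head", head)
        other = "left" if side == "right" else "right"
        ox = -sx
        o_shoulder = shoulder_center + np.array([ox * arm.shoulder_offset, 0.0, 0.0])
        add_static(f"shoulder_{other}", o_shoulder)
        hang = np.array([0.0, -1.0, 0.0])
        for joint, pos in chain(o_shoulder, np.tile(hang, (n, 1))).items():
            positions[f"{joint}_{other}"] = pos
    elif joints != "minimal":
        raise ValueError(f"joints must be 'upper' or 'minimal', got {joints!r}")

    labels = sorted(positions)  # fixed order for reproducible noise draws
    if noise.position_sd > 0 or noise.outlier_rate > 0:
        if rng is None:
            rng = np.random.default_rng(noise.seed)
        if noise.position_sd > 0:
            jitter = rng.normal(0.0, noise.position_sd, size=(n, len(labels), 3))
        else:
            jitter = np.zeros((n, len(labels), 3))
        if noise.outlier_rate > 0:
            hits = rng.random(size=(n, len(labels))) < noise.outlier_rate
            dirs = rng.normal(size=(n, len(labels), 3))
            norms = np.linalg.norm(dirs, axis=-1, keepdims=True)
            norms[norms == 0] = 1.0
            jitter += np.where(
                hits[..., None],
                dirs / norms * (noise.outlier_scale * noise.position_sd),
                0.0,
            )
        positions = {
            lab: positions[lab] + jitter[:, k, :] for k, lab in enumerate(labels)
        }
    return SkeletonSequence(t, positions, nominal_rate=fps)


def static_pose(
    angle_deg: float,
    plane: "str | AnatomicalPlane" = "coronal",
    n_frames: int = 30,
    fps: float = 30.0,
    **kwargs,
) -> SkeletonSequence:
    """A burst of ``n_frames`` frames holding one commanded angle."""
    return simulate_movement(
        constant(angle_deg), plane, fps=fps, duration=n_frames / fps, **kwargs
    )


# ---------------------------------------------------------------------------
# pipeline estimate shared by the protocols


def _pipeline_angle_estimate(
    seq: SkeletonSequence,
    articulation: str,
    side: str,
    plane,
    policy: "OutlierPolicy | None",
    smoothing: "SmoothingConfig | None",
) -> float:
    cleaned = preprocess_sequence(seq, policy=policy, cfg=smoothing)
    series = angle_series(cleaned, articulation, side, plane=plane)
    return float(np.nanmedian(series.theta))


# ---------------------------------------------------------------------------
# Protocol 1: static abduction ladder, goniometer vs pipeline


def protocol1_static(
    arm: "ArmModel | None" = None,
    noise: "NoiseConfig | None" = None,
    goniometer: "GoniometerModel | None" = None,
    step: float = 10.0,
    angle_range: tuple[float, float] = (0.0, 180.0),
    n_subjects: int = 9,
    frames_per_burst: int = 30,
    plane: str = "coronal",
    seed: "int | None" = None,
    outlier_policy: "OutlierPolicy | None" = None,
    smoothing: "SmoothingConfig | None" = None,
) -> PairedMeasurements:
    """Static agreement protocol: goniometer vs pipeline, both arms.

    Each subject (stature drawn from the cohort distribution) holds static
    abduction positions every ``step`` degrees across ``angle_range`` with
    each arm.  Method A is the simulated goniometer reading of the true
    angle; method B is the full pipeline estimate (static burst ->
    preprocessing -> coronal-plane abduction angle -> median over frames).
    Returns pairs ready for :func:`motionval.agreement.bland_altman`;
    default study size 9 subjects x 19 angles x 2 arms = 342 pairs.
    """
    noise = noise or NoiseConfig()
    goniometer = goniometer or GoniometerModel()
    lo, hi = angle_range
    if not step > 0 or not hi > lo:
        raise ValueError("step must be > 0 and angle_range increasing")
    n_steps = (hi - lo) / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"step {step} does not divide the range {angle_range}")
    angles = lo + step * np.arange(int(round(n_steps)) + 1)
    rng = np.random.default_rng(noise.seed if seed is None else seed)

    a_vals: list[float] = []
    b_vals: list[float] = []
    subjects: list[int] = []
    for subj in range(n_subjects):
        subj_arm = arm or ArmModel.from_height(
            max(rng.normal(COHORT_HEIGHT_M, COHORT_HEIGHT_SD_M), 1.2)
        )
        for side in ("left", "right"):
            for ang in angles:
                a_vals.append(goniometer.read(float(ang), rng))
                seq = simulate_movement(
                    constant(float(ang)),
                    plane,
                    arm=subj_arm,
                    noise=noise,
                    fps=30.0,
                    duration=frames_per_burst / 30.0,
                    side=side,
                    joints="minimal",
                    rng=rng,
                )
                b_vals.append(
                    _pipeline_angle_estimate(
                        seq, "shoulder_abduction", side, plane, outlier_policy, smoothing
                    )
                )
                subjects.append(subj)
    return PairedMeasurements(
        np.array(a_vals), np.array(b_vals), subject=np.array(subjects)
    )


# ---------------------------------------------------------------------------
# Protocol 2: repeated 90-degree flexion, two sessions

#: Per-session noise sd (degrees) reproducing the study's session-difference
#: dispersion sd(u) = 6.28 / 1.96 = 3.204 deg (sd(u) = sqrt(2) * session sd).
DEFAULT_SESSION_SD = 6.28 / 1.96 / math.sqrt(2.0)


def protocol2_sessions(
    arm: "ArmModel | None" = None,
    noise: "NoiseConfig | None" = None,
    session_sd: float = DEFAULT_SESSION_SD,
    n_subjects: int = 9,
    target: float = 90.0,
    planes: Iterable[str] = ("sagittal", "axial"),
    frames_per_burst: int = 30,
    seed: "int | None" = None,
    outlier_policy: "OutlierPolicy | None" = None,
    smoothing: "SmoothingConfig | None" = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Test-retest protocol: the same movement measured in two sessions.

    Each subject holds a ``target``-degree shoulder flexion in each listed
    plane; each session yields an independent pipeline estimate (3-D angle
    from the trunk-down reference) perturbed by session-level Gaussian noise
    of sd ``session_sd`` (posture re-assumption, repositioning, lighting).
    Returns ``(session1, session2)`` arrays ready for
    :func:`motionval.agreement.repeatability`.
    """
    if n_subjects < 2:
        raise ValueError(f"need at least 2 subjects, got {n_subjects}")
    if session_sd < 0:
        raise ValueError("session_sd must be >= 0")
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    planes = tuple(planes)

    s1: list[float] = []
    s2: list[float] = []
    for _subj in range(n_subjects):
        subj_arm = arm or ArmModel.from_height(
            max(rng.normal(COHORT_HEIGHT_M, COHORT_HEIGHT_SD_M), 1.2)
        )
        for plane in planes:
            sessions = []
            for _session in range(2):
                seq = simulate_movement(
                    constant(target),
                    plane,
                    arm=subj_arm,
                    noise=noise,
                    fps=30.0,
                    duration=frames_per_burst / 30.0,
                    side="right",
                    joints="minimal",
                    rng=rng,
                )
                est = _pipeline_angle_estimate(
                    seq, "shoulder_flexion", "right", None, outlier_policy, smoothing
                )
                if session_sd > 0:
                    est += rng.normal(0.0, session_sd)
                sessions.append(est)
            s1.append(sessions[0])
            s2.append(sessions[1])
    return np.array(s1), np.array(s2)
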