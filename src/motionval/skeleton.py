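"""Skeleton conventions shared by the whole pipeline.

Coordinates live in the depth-camera frame of a first-generation Kinect-class
sensor: **x** points to the camera's right, **y** up, **z** along the optical
axis away from the sensor.  Units are fixed by design and never configurable:
positions in meters, time in seconds, angles in degrees.  Single-unit
discipline prevents the silent conversion errors that plague clinical
pipelines.

The module defines

* the joint registries (20-joint standing skeleton, 10-joint seated subset),
* the three anatomical planes as axis projections of the camera frame,
* the five-segment upper-limb chain (trunk -> shoulder-line -> arm ->
  forearm -> hand) and the operations that extract segment vectors from
  frames and sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "STANDING_JOINTS",
    "SEATED_JOINTS",
    "UPPER_LIMB_JOINTS",
    "SIDES",
    "SEGMENT_NAMES",
    "AnatomicalPlane",
    "PLANES",
    "CORONAL",
    "SAGITTAL",
    "AXIAL",
    "resolve_plane",
    "project",
    "JointFrame",
    "SkeletonSequence",
    "SegmentVector",
    "segment_chain",
    "segment_vectors",
    "sequence_segment",
    "IncompleteFrameError",
]


class IncompleteFrameError(KeyError):
    """A frame lacks a joint required by the requested operation."""


#: Full standing skeleton (20 joints, Kinect v1 labels in lower snake case).
STANDING_JOINTS: tuple[str, ...] = (
    "hip_center",
    "spine",
    "shoulder_center",
    "head",
    "shoulder_left",
    "elbow_left",
    "wrist_left",
    "hand_left",
    "shoulder_right",
    "elbow_right",
    "wrist_right",
    "hand_right",
    "hip_left",
    "knee_left",
    "ankle_left",
    "foot_left",
    "hip_right",
    "knee_right",
    "ankle_right",
    "foot_right",
)

#: Seated tracking drops the pelvis, spine and legs; upper-limb joints are
#: unchanged, so every upper-limb operation applies to both registries.
SEATED_JOINTS: tuple[str, ...] = (
    "head",
    "shoulder_center",
    "shoulder_left",
    "elbow_left",
    "wrist_left",
    "hand_left",
    "shoulder_right",
    "elbow_right",
    "wrist_right",
    "hand_right",
)

UPPER_LIMB_JOINTS: tuple[str, ...] = tuple(
    j for j in STANDING_JOINTS if j in set(SEATED_JOINTS) | {"hip_center", "spine"}
)

KNOWN_JOINTS = frozenset(STANDING_JOINTS)

SIDES = ("left", "right")


@dataclass(frozen=True)
class AnatomicalPlane:
    """An anatomical plane expressed as a projection of the camera frame.

    ``kept_axes`` are the indices of the two coordinates retained by the
    projection (in fixed order); ``dropped_axis`` is the camera axis
    discarded.  Coronal keeps (x, y), sagittal keeps (y, z), axial keeps
    (x, z).
    """

    name: str
    kept_axes: tuple[int, int]
    dropped_axis: int


CORONAL = AnatomicalPlane("coronal", (0, 1), 2)
SAGITTAL = AnatomicalPlane("sagittal", (1, 2), 0)
AXIAL = AnatomicalPlane("axial", (0, 2), 1)

PLANES: Mapping[str, AnatomicalPlane] = {
    "coronal": CORONAL,
    "sagittal": SAGITTAL,
    "axial": AXIAL,
}


def resolve_plane(plane: "str | AnatomicalPlane | None") -> "AnatomicalPlane | None":
    """Normalise a plane argument; ``None``/``"3d"`` mean no projection."""
    if plane is None or isinstance(plane, AnatomicalPlane):
        return plane
    key = str(plane).lower()
    if key in ("3d", "none", ""):
        return None
    try:
        return PLANES[key]
    except KeyError:
        raise ValueError(
            f"unknown anatomical plane {plane!r}; expected one of "
            f"{sorted(PLANES)} or '3d'"
        ) from None


def project(v: np.ndarray, plane: AnatomicalPlane) -> np.ndarray:
    """Project 3-vectors onto an anatomical plane by dropping one axis.

    Accepts a single vector or an ``(n, 3)`` stack; returns the two kept
    coordinates in the plane's fixed order.
    """
    arr = np.asarray(v, dtype=float)
    return arr[..., list(plane.kept_axes)]


@dataclass(frozen=True)
class JointFrame:
    """Joint positions (meters, camera frame) at one instant ``t`` (seconds)."""

    t: float
    positions: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        if not np.isfinite(self.t) or self.t < 0:
            raise ValueError(f"frame time must be finite and non-negative, got {self.t}")
        for label, p in self.positions.items():
            if label not in KNOWN_JOINTS:
                raise ValueError(f"unknown joint label {label!r}")
            p = np.asarray(p, dtype=float)
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise ValueError(f"joint {label!r} needs a finite 3-vector, got {p!r}")

    def position(self, label: str) -> np.ndarray:
        try:
            return np.asarray(self.positions[label], dtype=float)
        except KeyError:
            raise IncompleteFrameError(
                f"incomplete frame: joint {label!r} missing at t={self.t}"
            ) from None


class SkeletonSequence:
    """Time-indexed 3D positions for a labelled joint set.

    Stored column-wise for speed: ``t`` is an ``(n,)`` strictly increasing
    array of seconds and ``positions`` maps each joint label to an ``(n, 3)``
    array of meters.  ``nominal_rate`` records the sensor frame rate
    (default 30 fps).
    """

    def __init__(
        self,
        t: np.ndarray,
        positions: Mapping[str, np.ndarray],
        nominal_rate: float = 30.0,
    ) -> None:
        t = np.asarray(t, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("t must be a non-empty 1-D array of seconds")
        if not np.all(np.isfinite(t)) or t[0] < 0:
            raise ValueError("t must be finite and non-negative")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("t must be strictly increasing")
        if not nominal_rate > 0:
            raise ValueError(f"nominal_rate must be positive, got {nominal_rate}")
        if not positions:
            raise ValueError("sequence needs at least one joint")
        pos: dict[str, np.ndarray] = {}
        for label, arr in positions.items():
            if label not in KNOWN_JOINTS:
                raise ValueError(f"unknown joint label {label!r}")
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (t.size, 3):
                raise ValueError(
                    f"joint {label!r}: expected shape {(t.size, 3)}, got {arr.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"joint {label!r} has non-finite coordinates")
            pos[label] = arr
        self.t = t
        self.positions = pos
        self.nominal_rate = float(nominal_rate)

    # -- container protocol -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return int(self.t.size)

    def __len__(self) -> int:
        return self.n_frames

    @property
    def joints(self) -> tuple[str, ...]:
        return tuple(sorted(self.positions))

    def frame(self, i: int) -> JointFrame:
        """Materialise frame ``i`` as a :class:`JointFrame` view."""
        return JointFrame(
            t=float(self.t[i]),
            positions={j: self.positions[j][i] for j in self.joints},
        )

    def __iter__(self) -> Iterator[JointFrame]:
        return (self.frame(i) for i in range(self.n_frames))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SkeletonSequence):
            return NotImplemented
        return (
            self.nominal_rate == other.nominal_rate
            and self.joints == other.joints
            and np.array_equal(self.t, other.t)
            and all(
                np.array_equal(self.positions[j], other.positions[j])
                for j in self.joints
            )
        )

    def with_positions(self, positions: Mapping[str, np.ndarray]) -> "SkeletonSequence":
        """Copy of this sequence with replaced coordinate arrays."""
        return SkeletonSequence(self.t.copy(), positions, self.nominal_rate)

    def __repr__(self) -> str:
        return (
            f"SkeletonSequence(n_frames={self.n_frames}, "
            f"joints={len(self.positions)}, rate={self.nominal_rate:g} fps)"
        )


@dataclass(frozen=True)
class SegmentVector:
    """A body-segment vector ``v = position(tip) - position(origin)``."""

    name: str
    origin_joint: str
    tip_joint: str
    v: np.ndarray


SEGMENT_NAMES = ("trunk", "shoulder_line", "arm", "forearm", "hand")


def segment_chain(side: str) -> tuple[tuple[str, str, str], ...]:
    """The fixed acyclic segment registry for one body side.

    Each entry is ``(segment_name, origin_joint, tip_joint)``; consecutive
    segments chain tip-to-origin from hip_center out to the hand.
    """
    if side not in SIDES:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return (
        ("trunk", "hip_center", "shoulder_center"),
        ("shoulder_line", "shoulder_center", f"shoulder_{side}"),
        ("arm", f"shoulder_{side}", f"elbow_{side}"),
        ("forearm", f"elbow_{side}", f"wrist_{side}"),
        ("hand", f"wrist_{side}", f"hand_{side}"),
    )


def segment_vectors(frame: JointFrame, side: str) -> list[SegmentVector]:
    """Build the five upper-limb segment vectors of one side from a frame.

    Raises :class:`IncompleteFrameError` naming the first missing joint.
    """
    out = []
    for name, origin, tip in segment_chain(side):
        v = frame.position(tip) - frame.position(origin)
        out.append(SegmentVector(name=name, origin_joint=origin, tip_joint=tip, v=v))
    return out


def sequence_segment(seq: SkeletonSequence, name: str, side: str) -> np.ndarray:
    """Vectorised segment extraction: ``(n, 3)`` array of tip - origin."""
    for seg_name, origin, tip in segment_chain(side):
        if seg_name == name:
            try:
                return seq.positions[tip] - seq.positions[origin]
            except KeyError as exc:
                raise IncompleteFrameError(
                    f"incomplete sequence: joint {exc.args[0]!r} missing"
                ) from None
    raise ValueError(f"unknown segment {name!r}; expected one of {SEGMENT_NAMES}")
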