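"""Joint angles and trajectory summaries from skeleton sequences.

The included angle between two body-segment vectors is

    theta = arccos( p1 . p2 / (||p1|| ||p2||) )

reported in degrees in [0, 180].  Clinical articulations are registered as
pairs of vector sources: either adjacent chain segments (elbow = arm vs
forearm) or a documented reference direction (shoulder abduction/flexion =
arm measured from the trunk-down direction, so an arm hanging at the side
reads 0 deg and an arm straight overhead reads 180 deg).

When an anatomical plane is requested, both vectors are projected onto the
plane first and the 2-D included angle is returned; frames where either
projected vector nearly vanishes are degenerate and marked missing (NaN)
rather than fabricated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .skeleton import (
    CORONAL,
    AnatomicalPlane,
    SkeletonSequence,
    project,
    resolve_plane,
    sequence_segment,
)

__all__ = [
    "DEFAULT_EPS",
    "DegenerateSegmentError",
    "joint_angle",
    "Articulation",
    "ARTICULATIONS",
    "register_articulation",
    "angle_series",
    "AngleSeries",
    "TrajectorySummary",
    "trajectory_summary",
]

#: Vectors with norm below this (meters) are treated as degenerate.
DEFAULT_EPS = 1e-9


class DegenerateSegmentError(ValueError):
    """A segment vector is too short to define a direction."""


def _angles_deg(v1: np.ndarray, v2: np.ndarray, eps: float = DEFAULT_EPS) -> np.ndarray:
    """Vectorised included angle; NaN where either vector is degenerate."""
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    ok = (n1 > eps) & (n2 > eps)
    dot = np.sum(v1 * v2, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cosang = np.where(ok, dot / np.where(ok, n1 * n2, 1.0), np.nan)
    cosang = np.clip(cosang, -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def joint_angle(p1, p2, eps: float = DEFAULT_EPS) -> float:
    """Included angle between two vectors, degrees in [0, 180].

    Symmetric in its arguments and invariant to positive scaling; the
    normalised inner product is clamped to [-1, 1] before ``arccos`` so
    floating-point overshoot never yields NaN.  Raises
    :class:`DegenerateSegmentError` naming the offending vector when either
    norm is below ``eps``.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape or p1.ndim != 1 or p1.size not in (2, 3):
        raise ValueError("joint_angle expects two 2- or 3-vectors of equal shape")
    if np.linalg.norm(p1) <= eps:
        raise DegenerateSegmentError("degenerate segment: first vector has near-zero norm")
    if np.linalg.norm(p2) <= eps:
        raise DegenerateSegmentError("degenerate segment: second vector has near-zero norm")
    return float(_angles_deg(p1, p2, eps))


# ---------------------------------------------------------------------------
# articulation registry


@dataclass(frozen=True)
class Articulation:
    """A named joint angle defined by two vector sources.

    Each source is either ``("segment", name)`` -- a chain segment of the
    requested side -- or ``("trunk_down",)`` -- the downward trunk direction
    (hip_center minus shoulder_center), the clinical reference for
    elevation-type shoulder angles.
    """

    name: str
    vector_a: tuple
    vector_b: tuple
    description: str = ""


ARTICULATIONS: dict[str, Articulation] = {}


def register_articulation(art: Articulation) -> None:
    ARTICULATIONS[art.name] = art


for _art in (
    Articulation(
        "elbow",
        ("segment", "arm"),
        ("segment", "forearm"),
        "included angle between upper arm and forearm (0 = fully folded)",
    ),
    Articulation(
        "wrist",
        ("segment", "forearm"),
        ("segment", "hand"),
        "included angle between forearm and hand segment",
    ),
    Articulation(
        "shoulder_abduction",
        ("trunk_down",),
        ("segment", "arm"),
        "arm elevation from the trunk-down reference; abduction when the "
        "movement runs in the coronal plane",
    ),
    Articulation(
        "shoulder_flexion",
        ("trunk_down",),
        ("segment", "arm"),
        "arm elevation from the trunk-down reference; flexion when the "
        "movement runs in the sagittal plane",
    ),
    Articulation(
        "shoulder_horizontal",
        ("segment", "shoulder_line"),
        ("segment", "arm"),
        "arm measured from the shoulder line; meaningful for horizontal "
        "(axial-plane) movements",
    ),
):
    register_articulation(_art)


def _resolve_vector(seq: SkeletonSequence, source: tuple, side: str) -> np.ndarray:
    kind = source[0]
    if kind == "segment":
        return sequence_segment(seq, source[1], side)
    if kind == "trunk_down":
        return -sequence_segment(seq, "trunk", side)
    raise ValueError(f"unknown vector source {source!r}")


@dataclass
class AngleSeries:
    """Per-frame joint angle trace with articulation metadata.

    ``theta`` is degrees in [0, 180] with NaN marking degenerate frames;
    ``plane`` is the plane name or ``"3d"``.
    """

    t: np.ndarray
    theta: np.ndarray
    joint: str
    side: str
    plane: str

    @property
    def n(self) -> int:
        return int(self.t.size)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n, dtype=int),
                "t": self.t,
                "joint": self.joint,
                "side": self.side,
                "plane": self.plane,
                "theta_deg": self.theta,
            }
        )


def angle_series(
    seq: SkeletonSequence,
    joint: str,
    side: str,
    plane: "str | AnatomicalPlane | None" = None,
    eps: float = DEFAULT_EPS,
) -> AngleSeries:
    """Compute a joint-angle trace, one angle per frame.

    ``joint`` names a registered articulation.  With a plane given, both
    defining vectors are projected first; degenerate frames (either vector
    shorter than ``eps``, e.g. elbow collocated with shoulder) are marked
    missing, never interpolated.
    """
    try:
        art = ARTICULATIONS[joint]
    except KeyError:
        raise ValueError(
            f"unknown articulation {joint!r}; registered: {sorted(ARTICULATIONS)}"
        ) from None
    p = resolve_plane(plane)
    v1 = _resolve_vector(seq, art.vector_a, side)
    v2 = _resolve_vector(seq, art.vector_b, side)
    if p is not None:
        v1 = project(v1, p)
        v2 = project(v2, p)
    theta = _angles_deg(v1, v2, eps)
    return AngleSeries(
        t=seq.t.copy(),
        theta=theta,
        joint=joint,
        side=side,
        plane=p.name if p is not None else "3d",
    )


# ---------------------------------------------------------------------------
# trajectory summaries


@dataclass
class TrajectorySummary:
    """Range of motion, covered area and path length of an end-effector path.

    ``rom`` is max minus min of the associated angle series (degrees);
    ``area`` the convex-hull area of the path projected to the requested
    plane (square meters); ``path_length`` the summed consecutive point
    distances (meters).
    """

    rom: float
    area: float
    path_length: float
    n_frames: int

    def to_report(self) -> dict:
        return {
            "rom_deg": self.rom,
            "area_m2": self.area,
            "path_length_m": self.path_length,
            "n_frames": self.n_frames,
        }


def _infer_side(end_effector: str) -> Optional[str]:
    for side in ("left", "right"):
        if end_effector.endswith(f"_{side}"):
            return side
    return None


def trajectory_summary(
    seq: SkeletonSequence,
    end_effector: str,
    plane: "str | AnatomicalPlane | None" = None,
    articulation: str = "shoulder_abduction",
    side: "str | None" = None,
) -> TrajectorySummary:
    """Summarise an end-effector trajectory.

    The covered area is the convex-hull area of the end-effector path
    projected to the given plane (for 3-D input the coronal projection is
    used -- a documented, parameter-free choice); fewer than three distinct
    non-collinear points give area 0 with a warning.  ROM comes from the
    articulation's angle series in the same plane; the side is inferred from
    the end-effector label unless given.
    """
    if end_effector not in seq.positions:
        raise ValueError(f"end effector {end_effector!r} not in sequence")
    side = side or _infer_side(end_effector)
    if side is None:
        raise ValueError(
            f"cannot infer body side from {end_effector!r}; pass side='left'|'right'"
        )
    p = resolve_plane(plane)
    pts3 = seq.positions[end_effector]
    pts = project(pts3, p) if p is not None else pts3
    steps = np.diff(pts, axis=0)
    path_length = float(np.linalg.norm(steps, axis=1).sum())

    hull_pts = pts if p is not None else project(pts3, CORONAL)
    area = 0.0
    unique = np.unique(np.round(hull_pts, 12), axis=0)
    if unique.shape[0] < 3:
        warnings.warn("fewer than 3 distinct points; covered area set to 0")
    else:
        try:
            # for a 2-D hull, `volume` is the enclosed area
            area = float(ConvexHull(hull_pts).volume)
        except QhullError:
            warnings.warn("collinear end-effector path; covered area set to 0")

    angles = angle_series(seq, articulation, side, plane=p)
    finite = angles.theta[np.isfinite(angles.theta)]
    rom = float(finite.max() - finite.min()) if finite.size else 0.0
    return TrajectorySummary(
        rom=rom, area=area, path_length=path_length, n_frames=seq.n_frames
    )
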