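"""CSV/JSON readers and writers, run configuration and session reports.

Schemas are strict by design: column names *and order* are part of the
contract, so a file produced by one tool in the chain is guaranteed to parse
identically in the next.  Malformed rows are rejected with 1-based line
numbers (header = line 1).

Formats
-------
skeleton CSV    ``frame,t,joint,x,y,z`` -- one row per joint per frame;
                meters/seconds, ``.`` decimal mark.
pairs CSV       ``subject,a,b`` (agreement) or
                ``subject,session1,session2`` (repeatability).
angle CSV       ``frame,t,joint,side,plane,theta_deg``.
report JSON     see :func:`motionval.agreement.agreement_report`.
config          flat ``key=value`` text, ``#`` comments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .agreement import PairedMeasurements
from .skeleton import KNOWN_JOINTS, SkeletonSequence

__all__ = [
    "DataError",
    "SKELETON_COLUMNS",
    "AGREEMENT_COLUMNS",
    "REPEATABILITY_COLUMNS",
    "read_skeleton_csv",
    "write_skeleton_csv",
    "read_pairs_csv",
    "write_pairs_csv",
    "write_report_json",
    "read_report_json",
    "read_config",
    "SessionReport",
    "append_session_report",
]

SKELETON_COLUMNS = ["frame", "t", "joint", "x", "y", "z"]
AGREEMENT_COLUMNS = ["subject", "a", "b"]
REPEATABILITY_COLUMNS = ["subject", "session1", "session2"]


class DataError(ValueError):
    """A file violates one of the documented schemas."""


def _check_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    if list(df.columns) != expected:
        raise DataError(
            f"{path}: expected header {','.join(expected)!r} "
            f"(in this order), got {','.join(map(str, df.columns))!r}"
        )


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    converted = pd.to_numeric(df[col], errors="coerce")
    bad = converted.isna() & df[col].notna()
    if bad.any() or converted.isna().any():
        idx = int((bad | converted.isna()).idxmax())
        raise DataError(
            f"{path}: non-numeric value {df[col].iloc[idx]!r} in column "
            f"{col!r} at line {idx + 2}"
        )
    return converted.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# skeleton CSV


def read_skeleton_csv(path, nominal_rate: float = 30.0) -> SkeletonSequence:
    """Parse a long-form skeleton CSV into a :class:`SkeletonSequence`.

    Every frame must list the same joint set; ``t`` must be constant within
    a frame and strictly increasing across frames.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    except Exception as exc:
        raise DataError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.empty:
        raise DataError(f"{path}: no data rows")
    _check_columns(df, SKELETON_COLUMNS, path)
    frame = _numeric(df, "frame", path)
    t = _numeric(df, "t", path)
    xyz = np.column_stack([_numeric(df, c, path) for c in ("x", "y", "z")])
    joints = df["joint"].to_numpy()
    for i, j in enumerate(joints):
        if j not in KNOWN_JOINTS:
            raise DataError(f"{path}: unknown joint {j!r} at line {i + 2}")

    frame_ids = np.unique(frame)
    joint_set = sorted(set(joints))
    n = frame_ids.size
    order = {f: k for k, f in enumerate(frame_ids)}
    t_arr = np.full(n, np.nan)
    positions = {j: np.full((n, 3), np.nan) for j in joint_set}
    for i in range(len(df)):
        k = order[frame[i]]
        if np.isfinite(t_arr[k]) and t_arr[k] != t[i]:
            raise DataError(
                f"{path}: inconsistent t within frame {int(frame[i])} at line {i + 2}"
            )
        t_arr[k] = t[i]
        if np.any(np.isfinite(positions[joints[i]][k])):
            raise DataError(
                f"{path}: duplicate joint {joints[i]!r} in frame "
                f"{int(frame[i])} at line {i + 2}"
            )
        positions[joints[i]][k] = xyz[i]
    for j, arr in positions.items():
        missing = np.flatnonzero(~np.isfinite(arr).all(axis=1))
        if missing.size:
            raise DataError(
                f"{path}: joint {j!r} missing in frame {int(frame_ids[missing[0]])}"
            )
    if n > 1 and not np.all(np.diff(t_arr) > 0):
        k = int(np.flatnonzero(np.diff(t_arr) <= 0)[0])
        raise DataError(
            f"{path}: t not strictly increasing between frames "
            f"{int(frame_ids[k])} and {int(frame_ids[k + 1])}"
        )
    try:
        return SkeletonSequence(t_arr, positions, nominal_rate=nominal_rate)
    except ValueError as exc:
        raise DataError(f"{path}: {exc}") from exc


def write_skeleton_csv(seq: SkeletonSequence, path) -> None:
    """Write a sequence in the long-form skeleton schema (lossless)."""
    joints = seq.joints
    n = seq.n_frames
    rows = {
        "frame": np.repeat(np.arange(n, dtype=int), len(joints)),
        "t": np.repeat(seq.t, len(joints)),
        "joint": np.tile(np.array(joints, dtype=object), n),
    }
    stacked = np.stack([seq.positions[j] for j in joints], axis=1).reshape(-1, 3)
    rows["x"], rows["y"], rows["z"] = stacked[:, 0], stacked[:, 1], stacked[:, 2]
    pd.DataFrame(rows, columns=SKELETON_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# paired-measurement CSV


def read_pairs_csv(path) -> tuple[str, PairedMeasurements]:
    """Read a paired-measurement table; returns ``(kind, pairs)``.

    ``kind`` is ``"agreement"`` for an ``a,b`` table or ``"repeatability"``
    for a ``session1,session2`` table.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    except Exception as exc:
        raise DataError(f"{path}: cannot parse CSV ({exc})") from exc
    cols = list(df.columns)
    if cols == AGREEMENT_COLUMNS:
        kind, c1, c2 = "agreement", "a", "b"
    elif cols == REPEATABILITY_COLUMNS:
        kind, c1, c2 = "repeatability", "session1", "session2"
    else:
        raise DataError(
            f"{path}: expected header {','.join(AGREEMENT_COLUMNS)!r} or "
            f"{','.join(REPEATABILITY_COLUMNS)!r}, got {','.join(map(str, cols))!r}"
        )
    if df.empty:
        raise DataError(f"{path}: no data rows")
    a = _numeric(df, c1, path)
    b = _numeric(df, c2, path)
    try:
        pairs = PairedMeasurements(a, b, subject=df["subject"].to_numpy())
    except ValueError as exc:
        raise DataError(f"{path}: {exc}") from exc
    return kind, pairs


def write_pairs_csv(pairs: PairedMeasurements, path, kind: str = "agreement") -> None:
    if kind == "agreement":
        cols = AGREEMENT_COLUMNS
    elif kind == "repeatability":
        cols = REPEATABILITY_COLUMNS
    else:
        raise ValueError(f"kind must be 'agreement' or 'repeatability', got {kind!r}")
    df = pairs.to_dataframe(a=cols[1], b=cols[2])
    df[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# reports and configuration


def write_report_json(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report_json(path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise DataError(f"{path}: invalid JSON ({exc})") from exc


def read_config(path) -> dict[str, str]:
    """Parse a flat ``key=value`` configuration file."""
    out: dict[str, str] = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise DataError(f"{path}: expected key=value at line {ln}, got {raw!r}")
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


@dataclass
class SessionReport:
    """Append-only clinical-history record for one measurement session."""

    subject_id: str
    software_version: str
    config: dict = field(default_factory=dict)
    angle_summaries: list = field(default_factory=list)
    agreement: Optional[dict] = None
    repeatability: Optional[dict] = None

    def to_json(self) -> dict:
        out = {
            "subject_id": self.subject_id,
            "software_version": self.software_version,
            "config": self.config,
            "angle_summaries": self.angle_summaries,
        }
        if self.agreement is not None:
            out["agreement"] = self.agreement
        if self.repeatability is not None:
            out["repeatability"] = self.repeatability
        return out


def append_session_report(report: SessionReport, path) -> None:
    """Append one session record as a JSON line; existing records are never mutated."""
    with open(path, "a") as fh:
        fh.write(json.dumps(report.to_json(), sort_keys=True) + "\n")
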