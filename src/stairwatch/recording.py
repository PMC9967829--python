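"""Session data model and on-disk session format.

A recording *session* is one person-present episode captured by a ceiling- or
wall-mounted RGB-D camera on a staircase: an ordered sequence of time-stamped
3-D skeleton frames (millimetres, camera coordinates, nominally 15 Hz) plus
metadata labels (participant id, ascent/descent, carried object).  Sessions
are stored as a directory containing a ``meta.json`` sidecar and a wide
``frames.csv`` table (one row per frame, three columns per joint), optionally
alongside a 16-bit ``depth.png`` used for stair-frame calibration.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NOMINAL_FRAME_RATE_HZ = 15.0

#: Azure-Kinect-style body tracking joint vocabulary (32 joints).
SKELETON_JOINTS = (
    "PELVIS", "SPINE_NAVEL", "SPINE_CHEST", "NECK",
    "CLAVICLE_LEFT", "SHOULDER_LEFT", "ELBOW_LEFT", "WRIST_LEFT",
    "HAND_LEFT", "HANDTIP_LEFT", "THUMB_LEFT",
    "CLAVICLE_RIGHT", "SHOULDER_RIGHT", "ELBOW_RIGHT", "WRIST_RIGHT",
    "HAND_RIGHT", "HANDTIP_RIGHT", "THUMB_RIGHT",
    "HIP_LEFT", "KNEE_LEFT", "ANKLE_LEFT", "FOOT_LEFT",
    "HIP_RIGHT", "KNEE_RIGHT", "ANKLE_RIGHT", "FOOT_RIGHT",
    "HEAD", "NOSE", "EYE_LEFT", "EAR_LEFT", "EYE_RIGHT", "EAR_RIGHT",
)

HAND_TRIPLETS = {
    "left": ("HAND_LEFT", "HANDTIP_LEFT", "THUMB_LEFT"),
    "right": ("HAND_RIGHT", "HANDTIP_RIGHT", "THUMB_RIGHT"),
}

CARRIED_LABELS = ("none", "material", "phone")
DIRECTION_LABELS = ("up", "down", "unknown")
GRASP_LABELS = ("grasped", "not_grasped", "unlabeled")
SPACE_LABELS = ("camera", "stair")


class SessionFormatError(ValueError):
    """A session directory is missing files or contains a malformed table."""


class EmptySessionError(SessionFormatError):
    """No valid frames survive ingestion."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Ideal pinhole parameters of the depth camera (no lens distortion).

    ``fx, fy`` are focal lengths and ``cx, cy`` the principal point, all in
    pixels; ``width, height`` give the image size.  The assembled 3x3 matrix
    maps metric rays to homogeneous pixel coordinates.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError(f"focal lengths must be positive, got fx={self.fx}, fy={self.fy}")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image size must be positive")

    @property
    def matrix(self) -> np.ndarray:
        """The 3x3 intrinsic matrix [[fx,0,cx],[0,fy,cy],[0,0,1]]."""
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    @property
    def inverse_matrix(self) -> np.ndarray:
        return np.array(
            [
                [1.0 / self.fx, 0.0, -self.cx / self.fx],
                [0.0, 1.0 / self.fy, -self.cy / self.fy],
                [0.0, 0.0, 1.0],
            ]
        )

    def to_dict(self) -> dict:
        return {
            "fx": self.fx, "fy": self.fy, "cx": self.cx, "cy": self.cy,
            "width": self.width, "height": self.height,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraIntrinsics":
        return cls(
            fx=float(d["fx"]), fy=float(d["fy"]),
            cx=float(d["cx"]), cy=float(d["cy"]),
            width=int(d["width"]), height=int(d["height"]),
        )


@dataclass
class SkeletonFrame:
    """One tracked body at one instant.

    ``joints`` maps joint names to finite 3-vectors in millimetres; a joint
    absent from the map is invalid for this frame.  The three hand joints of
    one side (HAND / HANDTIP / THUMB) are either all present or all absent —
    partial triplets are removed at ingestion.
    """

    timestamp: float
    joints: dict[str, np.ndarray]
    grasp_label: str = "unlabeled"

    def __post_init__(self) -> None:
        if self.grasp_label not in GRASP_LABELS:
            raise ValueError(f"unknown grasp label {self.grasp_label!r}")
        self.joints = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.joints.items()}

    def has(self, name: str) -> bool:
        return name in self.joints

    def joint(self, name: str) -> np.ndarray | None:
        return self.joints.get(name)

    def has_hand(self, side: str) -> bool:
        return all(self.has(j) for j in HAND_TRIPLETS[side])


@dataclass
class Session:
    """An ordered sequence of skeleton frames with session metadata."""

    frames: list[SkeletonFrame]
    intrinsics: CameraIntrinsics
    participant: str = "unknown"
    direction: str = "unknown"
    carried: str = "none"
    space: str = "camera"
    #: StairFrame provenance, set by ``to_stair_frame``; None in camera space.
    provenance: object | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.direction not in DIRECTION_LABELS:
            raise ValueError(f"unknown direction label {self.direction!r}")
        if self.carried not in CARRIED_LABELS:
            raise ValueError(f"unknown carried label {self.carried!r}")
        if self.space not in SPACE_LABELS:
            raise ValueError(f"unknown space tag {self.space!r}")
        if self.space == "camera" and self.provenance is not None:
            raise ValueError("camera-space session must not carry stair-frame provenance")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames])

    def joint_trajectory(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(times, positions)`` for the frames where ``name`` is valid."""
        t, p = [], []
        for f in self.frames:
            v = f.joint(name)
            if v is not None:
                t.append(f.timestamp)
                p.append(v)
        return np.array(t), np.array(p).reshape(-1, 3)

    def validate(self) -> None:
        """Raise if any type invariant is violated."""
        ts = self.timestamps
        if len(ts) and np.any(np.diff(ts) <= 0):
            raise SessionFormatError("timestamps are not strictly increasing")
        for f in self.frames:
            for name, v in f.joints.items():
                if not np.all(np.isfinite(v)):
                    raise SessionFormatError(f"non-finite joint {name} at t={f.timestamp}")
            for side in HAND_TRIPLETS:
                n = sum(f.has(j) for j in HAND_TRIPLETS[side])
                if n not in (0, 3):
                    raise SessionFormatError(f"partial {side} hand triplet at t={f.timestamp}")


@dataclass
class DepthMap:
    """A 16-bit depth image: each pixel is depth in millimetres, 0 = invalid."""

    data: np.ndarray
    intrinsics: CameraIntrinsics

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype != np.uint16:
            raise ValueError("depth map must be uint16 millimetres")
        h, w = self.data.shape
        if (w, h) != (self.intrinsics.width, self.intrinsics.height):
            raise ValueError(
                f"depth map shape {w}x{h} does not match intrinsics "
                f"{self.intrinsics.width}x{self.intrinsics.height}"
            )

    def save(self, path: str | Path) -> None:
        iio.imwrite(Path(path), self.data, extension=".png")

    @classmethod
    def load(cls, path: str | Path, intrinsics: CameraIntrinsics) -> "DepthMap":
        data = np.asarray(iio.imread(Path(path))).astype(np.uint16)
        return cls(data=data, intrinsics=intrinsics)


# ---------------------------------------------------------------------------
# Session directory I/O

_META_NAME = "meta.json"
_FRAMES_NAME = "frames.csv"


def _sanitize_frames(raw: list[SkeletonFrame]) -> tuple[list[SkeletonFrame], int]:
    """Enforce frame invariants, dropping what violates them.

    Returns the surviving frames and the number dropped.  Rules: non-finite
    joints are removed; a partial hand triplet loses its whole side; frames
    whose timestamp does not strictly increase are dropped; frames left with
    no valid joints are dropped.
    """
    dropped = 0
    out: list[SkeletonFrame] = []
    last_t = -math.inf
    for f in raw:
        joints = {
            k: v for k, v in f.joints.items() if np.all(np.isfinite(v))
        }
        for side, triplet in HAND_TRIPLETS.items():
            n = sum(j in joints for j in triplet)
            if 0 < n < 3:
                for j in triplet:
                    joints.pop(j, None)
        if not joints or not (f.timestamp > last_t) or not math.isfinite(f.timestamp):
            dropped += 1
            continue
        last_t = f.timestamp
        out.append(SkeletonFrame(timestamp=f.timestamp, joints=joints, grasp_label=f.grasp_label))
    return out, dropped


def save_session(session: Session, path: str | Path) -> None:
    """Write a session directory (``meta.json`` + ``frames.csv``).

    Joint coordinates are written with 17 significant digits so that a
    save→load round trip preserves them bit-for-bit.
    """
    if not session.frames:
        raise EmptySessionError("refusing to save a session with no frames")
    session.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    meta = {
        "participant": session.participant,
        "direction": session.direction,
        "carried": session.carried,
        "space": session.space,
        "intrinsics": session.intrinsics.to_dict(),
    }
    if session.provenance is not None:
        meta["stair_frame"] = session.provenance.to_dict()
    (path / _META_NAME).write_text(json.dumps(meta, indent=2))

    joint_names = sorted({n for f in session.frames for n in f.joints})
    rows = []
    for f in session.frames:
        row: dict[str, object] = {"timestamp": f.timestamp, "grasp_label": f.grasp_label}
        for name in joint_names:
            v = f.joint(name)
            for axis, val in zip("xyz", v if v is not None else (np.nan,) * 3):
                row[f"{name}_{axis}"] = val
        rows.append(row)
    pd.DataFrame(rows).to_csv(path / _FRAMES_NAME, index=False, float_format="%.17g")


def load_session(path: str | Path) -> Session:
    """Load and validate a session directory.

    Frames violating invariants (non-finite joints, partial hand triplets,
    non-monotone timestamps) are dropped with a logged count.
    """
    path = Path(path)
    meta_path, frames_path = path / _META_NAME, path / _FRAMES_NAME
    if not meta_path.is_file() or not frames_path.is_file():
        raise SessionFormatError(f"{path} is not a session directory (need meta.json + frames.csv)")
    try:
        meta = json.loads(meta_path.read_text())
        table = pd.read_csv(frames_path, float_precision="round_trip")
    except (json.JSONDecodeError, pd.errors.ParserError) as exc:
        raise SessionFormatError(f"corrupt session files in {path}: {exc}") from exc
    if "timestamp" not in table.columns:
        raise SessionFormatError("frames.csv lacks a timestamp column")

    joint_names = sorted(
        {c[:-2] for c in table.columns if c.endswith(("_x", "_y", "_z"))}
    )
    raw: list[SkeletonFrame] = []
    for _, row in table.iterrows():
        joints = {}
        for name in joint_names:
            v = np.array([row.get(f"{name}_{ax}", np.nan) for ax in "xyz"], dtype=float)
            if np.all(np.isfinite(v)):
                joints[name] = v
            elif np.any(np.isfinite(v)):
                # partially recorded joint: treat as invalid
                pass
        label = row.get("grasp_label", "unlabeled")
        if not isinstance(label, str) or label not in GRASP_LABELS:
            label = "unlabeled"
        raw.append(SkeletonFrame(timestamp=float(row["timestamp"]), joints=joints, grasp_label=label))

    frames, dropped = _sanitize_frames(raw)
    if dropped:
        logger.warning("%s: dropped %d invalid frame(s)", path, dropped)
        warnings.warn(f"{path}: dropped {dropped} invalid frame(s)", stacklevel=2)
    if not frames:
        raise EmptySessionError(f"{path}: no valid frames")

    session = Session(
        frames=frames,
        intrinsics=CameraIntrinsics.from_dict(meta["intrinsics"]),
        participant=str(meta.get("participant", "unknown")),
        direction=str(meta.get("direction", "unknown")),
        carried=str(meta.get("carried", "none")),
        space=str(meta.get("space", "camera")),
    )
    if "stair_frame" in meta and session.space == "stair":
        from .stairframe import StairFrame  # local import to avoid a cycle

        session.provenance = StairFrame.from_dict(meta["stair_frame"])
    session.validate()
    return session


def filter_by_labels(session: Session, carried: str) -> Session | None:
    """Select the session if its carried-object label matches, else None.

    Downstream analyses consider only sessions where nothing was carried
    (label ``none``), since a held object changes hand availability.
    """
    if carried not in CARRIED_LABELS:
        raise ValueError(f"unknown carried label {carried!r}")
    return session if session.carried == carried else None


def filter_sessions(sessions: list[Session], carried: str = "none") -> list[Session]:
    """Collection-level carried-object filter (keeps order)."""
    return [s for s in sessions if filter_by_labels(s, carried) is not None]


def copy_session(session: Session, **changes) -> Session:
    """Shallow-copy a session with metadata changes (frames list is re-built)."""
    frames = [
        SkeletonFrame(
            timestamp=f.timestamp,
            joints={k: v.copy() for k, v in f.joints.items()},
            grasp_label=f.grasp_label,
        )
        for f in session.frames
    ]
    return replace(session, frames=frames, **changes)
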