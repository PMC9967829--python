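"""Stair-local coordinate frame: wall-plane fit, basis construction, transform.

Motions recorded in camera coordinates are re-expressed in a right-handed
*stair frame*: x along the handrail's long axis (pointing up-slope), y the
wall-normal (lateral) direction, z the remaining orthogonal axis, with the
origin at a handrail edge point P0.  The frame is built from three scene
landmarks picked once per installation: two handrail pixels (giving the axis
nx), a rectangular wall region (whose least-squares plane gives the normal
seed ny'), and the origin pixel.

The wall plane is fit by ordinary least squares on ``[X, Y, 1] [a b d]^T =
-Z`` (the c coefficient normalized to 1), so the normal seed is (a, b, 1),
sign-oriented toward the camera.  The basis is orthonormalized by two cross
products: nz = nx x ny', then ny = nz x nx.  The camera->stair map is
``q = R (p - P0)`` with R's rows (nx, ny, nz); as a homogeneous matrix
``H = [R, -R P0; 0 1]``, so P0 lands on the stair-frame origin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .camera import back_project, back_project_region
from .recording import DepthMap, Session, SkeletonFrame, copy_session

_ORTHO_TOL = 1e-9
_MIN_HANDRAIL_SEPARATION_MM = 10.0
_NEAR_PARALLEL_DOT = 0.99


class DegenerateFitError(ValueError):
    """The wall point cloud is rank-deficient (collinear or too small)."""


class CalibrationError(ValueError):
    """Calibration landmarks are missing, degenerate or inconsistent."""


@dataclass(frozen=True)
class PlaneFit:
    """Least-squares wall plane ``a X + b Y + Z + d = 0`` (c normalized to 1)."""

    a: float
    b: float
    d: float
    rms_residual: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("a plane fit needs at least 3 points")
        if self.rms_residual < 0:
            raise ValueError("rms residual must be non-negative")

    @property
    def normal(self) -> np.ndarray:
        """Unit wall normal (a, b, 1)/||.||, sign not yet oriented."""
        n = np.array([self.a, self.b, 1.0])
        return n / np.linalg.norm(n)


def fit_wall_plane(cloud: np.ndarray) -> PlaneFit:
    """Fit a plane to a wall point cloud by the normal-equations least squares.

    Solves ``[a b d]^T = -(P'^T P')^-1 P'^T Z`` with ``P' = [X, Y, 1]``,
    i.e. minimizes the vertical (Z) residuals of ``a X + b Y + Z + d``.
    Valid whenever the wall is not edge-on to the camera (c != 0), which
    holds for any wall the depth camera can image as a region.
    """
    pts = np.asarray(cloud, dtype=float).reshape(-1, 3)
    if pts.shape[0] < 3:
        raise DegenerateFitError("need at least 3 points to fit a plane")
    P = np.column_stack([pts[:, 0], pts[:, 1], np.ones(len(pts))])
    Z = pts[:, 2]
    # rank check on the design matrix: collinear (X, Y) footprints are degenerate
    if np.linalg.matrix_rank(P, tol=1e-6 * max(1.0, np.abs(P).max())) < 3:
        raise DegenerateFitError("wall points are collinear in the image plane")
    coef, *_ = np.linalg.lstsq(P, -Z, rcond=None)
    a, b, d = (float(c) for c in coef)
    resid = P @ coef + Z
    rms = float(np.sqrt(np.mean(resid**2)))
    return PlaneFit(a=a, b=b, d=d, rms_residual=rms, n_points=len(pts))


def handrail_axis(p_start: np.ndarray, p_end: np.ndarray) -> np.ndarray:
    """Unit vector from the downhill to the uphill handrail endpoint.

    By convention ``p_start`` is the downhill end, so +x points up-slope and
    a pelvis ascending the stairs has increasing stair-x.
    """
    p_start = np.asarray(p_start, dtype=float).reshape(3)
    p_end = np.asarray(p_end, dtype=float).reshape(3)
    delta = p_end - p_start
    norm = np.linalg.norm(delta)
    if norm <= _MIN_HANDRAIL_SEPARATION_MM:
        raise CalibrationError(
            f"handrail endpoints are {norm:.1f} mm apart; need > {_MIN_HANDRAIL_SEPARATION_MM} mm"
        )
    return delta / norm


def orient_normal_toward_camera(normal: np.ndarray, cloud_centroid: np.ndarray) -> np.ndarray:
    """Fix the wall-normal sign so it points from the wall toward the camera.

    The camera sits at the origin of camera space, so the oriented normal
    must have a non-negative dot product with (origin - centroid).
    """
    normal = np.asarray(normal, dtype=float).reshape(3)
    toward_camera = -np.asarray(cloud_centroid, dtype=float).reshape(3)
    if float(normal @ toward_camera) < 0:
        return -normal
    return normal


def build_basis(nx: np.ndarray, ny_raw: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormalize the handrail axis and wall-normal seed into a basis.

    ``nz = nx x ny'`` (normalized), then ``ny = nz x nx``; the result is an
    exactly orthonormal, right-handed triple with nx preserved.
    """
    nx = np.asarray(nx, dtype=float).reshape(3)
    ny_raw = np.asarray(ny_raw, dtype=float).reshape(3)
    nx = nx / np.linalg.norm(nx)
    ny_raw = ny_raw / np.linalg.norm(ny_raw)
    cos_angle = float(nx @ ny_raw)
    if abs(cos_angle) >= _NEAR_PARALLEL_DOT:
        angle_deg = float(np.degrees(np.arccos(np.clip(abs(cos_angle), -1, 1))))
        raise CalibrationError(
            f"handrail axis and wall normal are only {angle_deg:.2f} deg apart; "
            "basis would be numerically meaningless"
        )
    nz = np.cross(nx, ny_raw)
    nz = nz / np.linalg.norm(nz)
    ny = np.cross(nz, nx)
    return nx, ny, nz


@dataclass(frozen=True)
class StairFrame:
    """Rigid camera->stair transform: rotation R (rows nx, ny, nz) and origin P0.

    Application maps a camera-space point p to stair coordinates
    ``q = R (p - P0)``; the 4x4 homogeneous form is ``H = [R, -R P0; 0 1]``.
    """

    origin: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))
        object.__setattr__(self, "R", np.asarray(self.R, dtype=float).reshape(3, 3))
        gram = self.R @ self.R.T
        if np.max(np.abs(gram - np.eye(3))) > 1e-8:
            raise ValueError("rotation rows are not orthonormal")
        if abs(np.linalg.det(self.R) - 1.0) > 1e-8:
            raise ValueError("rotation must be right-handed (det = +1)")

    @property
    def nx(self) -> np.ndarray:
        return self.R[0]

    @property
    def ny(self) -> np.ndarray:
        return self.R[1]

    @property
    def nz(self) -> np.ndarray:
        return self.R[2]

    @property
    def H(self) -> np.ndarray:
        """4x4 homogeneous camera->stair matrix."""
        H = np.eye(4)
        H[:3, :3] = self.R
        H[:3, 3] = -self.R @ self.origin
        return H

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map camera-space point(s) (mm) into stair coordinates."""
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        q = (np.atleast_2d(p) - self.origin) @ self.R.T
        return q[0] if single else q

    def invert(self, points: np.ndarray) -> np.ndarray:
        """Map stair-space point(s) back to camera coordinates."""
        q = np.asarray(points, dtype=float)
        single = q.ndim == 1
        p = np.atleast_2d(q) @ self.R + self.origin
        return p[0] if single else p

    def to_dict(self) -> dict:
        return {"origin": self.origin.tolist(), "R": self.R.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "StairFrame":
        return cls(origin=np.array(d["origin"], dtype=float), R=np.array(d["R"], dtype=float))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "StairFrame":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_transform(basis: tuple[np.ndarray, np.ndarray, np.ndarray], p0: np.ndarray) -> StairFrame:
    """Assemble a StairFrame from an orthonormal basis and the origin P0."""
    nx, ny, nz = (np.asarray(v, dtype=float).reshape(3) for v in basis)
    R = np.vstack([nx, ny, nz])
    try:
        return StairFrame(origin=np.asarray(p0, dtype=float).reshape(3), R=R)
    except ValueError as exc:
        raise CalibrationError(str(exc)) from exc


def to_stair_frame(session: Session, frame: StairFrame) -> Session:
    """Transform every joint of every frame into stair coordinates.

    Returns a new session tagged ``space='stair'`` with the StairFrame
    recorded as provenance; the input must be in camera space.
    """
    if session.space != "camera":
        raise ValueError("session is already in stair space")
    out = copy_session(session)
    for f in out.frames:
        for name, v in f.joints.items():
            f.joints[name] = frame.apply(v)
    out.space = "stair"
    out.provenance = frame
    return out


# ---------------------------------------------------------------------------
# Calibration from depth-map landmarks

def load_calibration(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _landmark_point(calib: dict, key: str, depth_map: DepthMap | None) -> np.ndarray:
    """Resolve a landmark to a camera-space 3-D point.

    Accepts either ``<key>_xyz`` (direct millimetre coordinates) or
    ``<key>_px`` with an optional ``<key>_depth`` (else the depth is read
    from the depth map at that pixel).
    """
    if f"{key}_xyz" in calib:
        return np.asarray(calib[f"{key}_xyz"], dtype=float).reshape(3)
    if f"{key}_px" not in calib:
        raise CalibrationError(f"calibration lacks {key}_xyz or {key}_px")
    if depth_map is None:
        raise CalibrationError(f"{key}_px landmark requires a depth map")
    u, v = (float(x) for x in calib[f"{key}_px"])
    depth = calib.get(f"{key}_depth")
    if depth is None:
        depth = float(depth_map.data[int(round(v)), int(round(u))])
        if depth <= 0:
            raise CalibrationError(f"depth map has no valid depth at {key}_px=({u}, {v})")
    return back_project((u, v), float(depth), depth_map.intrinsics)


def build_stair_frame(calib: dict, depth_map: DepthMap | None = None) -> tuple[StairFrame, PlaneFit | None]:
    """Build the stair frame from a calibration record.

    The record supplies the handrail start (downhill) and end landmarks, the
    origin landmark (defaults to the handrail start), and either a wall
    rectangle ``wall_rect = [u0, v0, u1, v1]`` on the depth map or a direct
    ``wall_normal`` vector.  ``flip_lateral: true`` negates the wall-normal
    seed before orthonormalization for installations where the oriented
    z-axis would otherwise point up instead of down.

    Returns the frame and the wall-plane fit (None if a direct normal was
    given).
    """
    p_start = _landmark_point(calib, "handrail_start", depth_map)
    p_end = _landmark_point(calib, "handrail_end", depth_map)
    nx = handrail_axis(p_start, p_end)

    fit: PlaneFit | None = None
    if "wall_normal" in calib:
        ny_raw = np.asarray(calib["wall_normal"], dtype=float).reshape(3)
        ny_raw = ny_raw / np.linalg.norm(ny_raw)
    elif "wall_rect" in calib:
        if depth_map is None:
            raise CalibrationError("wall_rect calibration requires a depth map")
        cloud = back_project_region(depth_map, tuple(calib["wall_rect"]))
        fit = fit_wall_plane(cloud)
        ny_raw = orient_normal_toward_camera(fit.normal, cloud.mean(axis=0))
    else:
        raise CalibrationError("calibration lacks wall_rect or wall_normal")

    if calib.get("flip_lateral", False):
        ny_raw = -ny_raw

    basis = build_basis(nx, ny_raw)
    if "origin_xyz" in calib or "origin_px" in calib:
        p0 = _landmark_point(calib, "origin", depth_map)
    else:
        p0 = p_start
    return build_transform(basis, p0), fit
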