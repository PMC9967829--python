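"""Synthetic staircase scenes, depth maps, and skeleton traversals.

No public recordings of in-home stair use exist, so every pipeline stage is
exercised against a generator that emulates the measurement setup: a planar
wall carrying a straight handrail, imaged by a pinhole depth camera, and a
walker whose pelvis moves along the stair slope at constant 3-D speed while
one hand grasps the rail during configurable episodes.  The generator
returns ground truth (true wall normal, rail axis, speed, direction,
per-frame grasp flags) sufficient to score every downstream operation.

Simplifications, by design: the pelvis path is a constant-slope ramp (no
per-step oscillation unless requested), joint noise is isotropic Gaussian
per joint per frame, and depth noise is independent per pixel.  All
randomness flows from the per-call seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import (
    NOMINAL_FRAME_RATE_HZ,
    CameraIntrinsics,
    DepthMap,
    Session,
    SkeletonFrame,
)
from .stairframe import StairFrame, build_basis, build_transform, handrail_axis

#: Azure-Kinect-like depth intrinsics (NFOV unbinned geometry, scaled).
DEFAULT_INTRINSICS = CameraIntrinsics(fx=505.0, fy=505.0, cx=320.0, cy=288.0, width=640, height=576)


class SceneGeometryError(ValueError):
    """Scene landmarks are out of view or degenerate."""


@dataclass(frozen=True)
class SceneSpec:
    """Geometry of a synthetic staircase as seen from the camera.

    All coordinates are camera space, millimetres (x right, y down,
    z forward).  ``wall_normal`` points from the wall toward the camera;
    ``rail_start`` is the downhill handrail end and doubles as the stair-
    frame origin.
    """

    intrinsics: CameraIntrinsics = DEFAULT_INTRINSICS
    wall_normal: tuple[float, float, float] = (-0.148, -0.049, -0.988)
    wall_point: tuple[float, float, float] = (-700.0, 400.0, 2460.0)
    rail_start: tuple[float, float, float] = (-700.0, 400.0, 2400.0)
    rail_end: tuple[float, float, float] = (828.8, -482.0, 2047.2)
    rail_radius: float = 20.0
    depth_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        s, e = np.array(self.rail_start), np.array(self.rail_end)
        if s[2] <= 0 or e[2] <= 0:
            raise SceneGeometryError("handrail endpoints must be in front of the camera")
        axis = (e - s) / np.linalg.norm(e - s)
        if abs(axis[2]) > 0.95:
            raise SceneGeometryError("handrail must not be parallel to the view axis")

    @property
    def rail_axis(self) -> np.ndarray:
        """True unit up-slope axis (downhill -> uphill endpoint)."""
        return handrail_axis(np.array(self.rail_start), np.array(self.rail_end))

    @property
    def rail_length(self) -> float:
        return float(np.linalg.norm(np.array(self.rail_end) - np.array(self.rail_start)))

    @property
    def unit_wall_normal(self) -> np.ndarray:
        n = np.asarray(self.wall_normal, dtype=float)
        return n / np.linalg.norm(n)

    def stair_frame(self) -> StairFrame:
        """The exact ground-truth stair frame of this scene."""
        basis = build_basis(self.rail_axis, self.unit_wall_normal)
        return build_transform(basis, np.array(self.rail_start))


@dataclass(frozen=True)
class SceneLandmarks:
    """Ground truth returned alongside a rendered depth map."""

    rail_px_start: tuple[int, int]
    rail_px_end: tuple[int, int]
    wall_rect: tuple[int, int, int, int]
    origin_px: tuple[int, int]
    true_axis: np.ndarray
    true_normal: np.ndarray

    def calibration(self) -> dict:
        """A calibration record usable with ``build_stair_frame``."""
        return {
            "handrail_start_px": list(self.rail_px_start),
            "handrail_end_px": list(self.rail_px_end),
            "origin_px": list(self.origin_px),
            "wall_rect": list(self.wall_rect),
        }


def _project_px(p: np.ndarray, intr: CameraIntrinsics) -> np.ndarray:
    return np.array([intr.fx * p[0] / p[2] + intr.cx, intr.fy * p[1] / p[2] + intr.cy])


def make_depth_map(scene: SceneSpec, seed: int | None = None) -> tuple[DepthMap, SceneLandmarks]:
    """Render a 16-bit depth image of the wall plane and handrail.

    The wall fills the view; the rail is drawn as a thick segment whose
    surface sits ``rail_radius`` in front of its axis.  Per-pixel Gaussian
    depth noise (``scene.depth_noise_sd``) and 1 mm quantization are
    applied.  Returns the map plus ground-truth landmarks: integer rail
    endpoint pixels, a rail-free wall rectangle, the origin pixel, and the
    true axis and normal.
    """
    intr = scene.intrinsics
    n = scene.unit_wall_normal
    offset = float(n @ np.asarray(scene.wall_point, dtype=float))

    uu, vv = np.meshgrid(np.arange(intr.width), np.arange(intr.height))
    dir_x = (uu - intr.cx) / intr.fx
    dir_y = (vv - intr.cy) / intr.fy
    denom = n[0] * dir_x + n[1] * dir_y + n[2]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = offset / denom
    z = np.where((denom != 0) & (z > 100.0) & (z < 60000.0), z, 0.0)

    # handrail: thick 2-D segment, depth interpolated along the axis
    s3, e3 = np.asarray(scene.rail_start, dtype=float), np.asarray(scene.rail_end, dtype=float)
    s2, e2 = _project_px(s3, intr), _project_px(e3, intr)
    if not (
        0 <= s2[0] < intr.width and 0 <= s2[1] < intr.height
        and 0 <= e2[0] < intr.width and 0 <= e2[1] < intr.height
    ):
        raise SceneGeometryError("handrail is not fully inside the camera view")
    seg = e2 - s2
    seg_len2 = float(seg @ seg)
    t_par = ((uu - s2[0]) * seg[0] + (vv - s2[1]) * seg[1]) / seg_len2
    t_clip = np.clip(t_par, 0.0, 1.0)
    du = uu - (s2[0] + t_clip * seg[0])
    dv = vv - (s2[1] + t_clip * seg[1])
    dist2d = np.hypot(du, dv)
    z_axis = s3[2] + t_clip * (e3[2] - s3[2])
    radius_px = scene.rail_radius * intr.fx / z_axis
    on_rail = dist2d <= radius_px
    z_rail = z_axis - scene.rail_radius
    z = np.where(on_rail & ((z == 0) | (z_rail < z)), z_rail, z)

    if scene.depth_noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, scene.depth_noise_sd, z.shape)
        z = np.where(z > 0, z + noise, 0.0)
    depth = DepthMap(data=np.clip(np.round(z), 0, 65535).astype(np.uint16), intrinsics=intr)

    # landmark pixels: rail endpoints pulled slightly inward so the rounded
    # pixel is guaranteed to lie on the rendered rail
    p_in_s = _project_px(s3 + 0.02 * (e3 - s3), intr)
    p_in_e = _project_px(e3 - 0.02 * (e3 - s3), intr)
    rail_px_start = (int(round(p_in_s[0])), int(round(p_in_s[1])))
    rail_px_end = (int(round(p_in_e[0])), int(round(p_in_e[1])))

    wall_rect = _find_wall_rect(depth, s2, e2, float(np.max(radius_px)))
    landmarks = SceneLandmarks(
        rail_px_start=rail_px_start,
        rail_px_end=rail_px_end,
        wall_rect=wall_rect,
        origin_px=rail_px_start,
        true_axis=scene.rail_axis,
        true_normal=scene.unit_wall_normal,
    )
    return depth, landmarks


def _find_wall_rect(
    depth: DepthMap, s2: np.ndarray, e2: np.ndarray, radius_px: float, size: int = 90
) -> tuple[int, int, int, int]:
    """Pick a ``size`` x ``size`` rectangle of pure wall pixels near the rail."""
    intr = depth.intrinsics
    mid = (s2 + e2) / 2.0
    seg = e2 - s2
    perp = np.array([-seg[1], seg[0]]) / np.linalg.norm(seg)
    for sign in (1.0, -1.0):
        for dist in (radius_px + 80, radius_px + 150, radius_px + 250):
            c = mid + sign * dist * perp
            u0, v0 = int(c[0] - size / 2), int(c[1] - size / 2)
            u1, v1 = u0 + size, v0 + size
            if not (0 <= u0 < u1 <= intr.width and 0 <= v0 < v1 <= intr.height):
                continue
            uu, vv = np.meshgrid(np.arange(u0, u1), np.arange(v0, v1))
            t_par = ((uu - s2[0]) * seg[0] + (vv - s2[1]) * seg[1]) / float(seg @ seg)
            t_clip = np.clip(t_par, 0.0, 1.0)
            d = np.hypot(uu - (s2[0] + t_clip * seg[0]), vv - (s2[1] + t_clip * seg[1]))
            patch = depth.data[v0:v1, u0:u1]
            if np.all(patch > 0) and np.min(d) > radius_px + 10:
                return (u0, v0, u1, v1)
    raise SceneGeometryError("could not place a rail-free wall rectangle in view")


@dataclass(frozen=True)
class TraversalSpec:
    """One synthetic stair traversal.

    ``grasp_episodes`` are (start, end) fractions of the traversal time
    during which the hand triplet sits on the handrail surface; outside
    episodes the hand stays near the pelvis, well clear (>= 150 mm) of the
    rail.  ``x_start``/``x_end`` bound the pelvis path in stair-x (mm); they
    must bracket the 0–1000 mm measurement window.
    """

    direction: str = "up"
    speed: float = 0.5  # m/s, 3-D pelvis speed
    duration: float | None = None  # s; derived from the x-range if None
    frame_rate: float = NOMINAL_FRAME_RATE_HZ
    grasp_episodes: tuple[tuple[float, float], ...] = ()
    joint_noise_sd: float = 0.0
    seed: int = 0
    x_start: float = -300.0
    x_end: float = 1300.0
    side: str = "right"
    pelvis_offset: tuple[float, float] = (350.0, 850.0)  # stair (y, z) mm
    step_amplitude: float = 0.0  # optional per-step pelvis oscillation, mm

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be up or down")
        if not self.speed > 0:
            raise ValueError("speed must be positive")
        last = -1.0
        for s, e in self.grasp_episodes:
            if not (0.0 <= s < e <= 1.0) or s < last:
                raise ValueError("grasp episodes must be non-overlapping fractions in [0, 1]")
            last = e


@dataclass(frozen=True)
class TraversalTruth:
    """Ground-truth bundle for one simulated traversal."""

    direction: str
    speed: float
    frame_grasp: np.ndarray  # bool per frame
    pgp_stair: np.ndarray  # (N, 3) noise-free grasp points, stair mm
    pelvis_stair: np.ndarray  # (N, 3) noise-free pelvis, stair mm
    times: np.ndarray
    stair_frame: StairFrame = field(repr=False, default=None)


def segment_coverage_episode(
    spec: TraversalSpec, fraction: float, segment: tuple[float, float] = (0.0, 1000.0)
) -> tuple[tuple[float, float], ...]:
    """One grasp episode whose in-segment time coverage equals ``fraction``.

    Converts the stair-x segment bounds into traversal-time fractions for
    ``spec`` and returns an episode starting at segment entry covering the
    requested share of the in-segment time.
    """
    span = spec.x_end - spec.x_start
    s0 = (segment[0] - spec.x_start) / span
    s1 = (segment[1] - spec.x_start) / span
    if spec.direction == "down":
        s0, s1 = 1.0 - s1, 1.0 - s0
    return ((s0, s0 + fraction * (s1 - s0)),)


def simulate_traversal(
    scene: SceneSpec,
    spec: TraversalSpec,
    label_grasps: bool = False,
    participant: str = "sim",
) -> tuple[Session, TraversalTruth]:
    """Simulate one stair traversal in front of a synthetic scene.

    The pelvis travels the stair-x range at constant 3-D speed ``spec.speed``
    (slope direction = rail axis = stair +x), reversed for a descent.  The
    configured hand's HAND/HANDTIP/THUMB joints lie on the handrail surface
    during grasp episodes and near the pelvis otherwise; the opposite hand
    never grasps.  Isotropic Gaussian noise ``joint_noise_sd`` is applied to
    every joint, and all joints are expressed in camera coordinates.

    Returns a camera-space :class:`Session` (grasp labels attached when
    ``label_grasps``) and the :class:`TraversalTruth` bundle.
    """
    frame = scene.stair_frame()
    span = spec.x_end - spec.x_start
    speed_mm = spec.speed * 1000.0
    duration = spec.duration if spec.duration is not None else span / speed_mm
    x_reach = spec.x_start + speed_mm * duration
    if x_reach <= 1000.0 + 50.0:
        raise ValueError(
            f"duration {duration:.2f} s too short: pelvis reaches x={x_reach:.0f} mm "
            "and never clears the 0-1000 mm window"
        )
    n_frames = int(np.floor(duration * spec.frame_rate)) + 1
    t = np.arange(n_frames) / spec.frame_rate
    frac = t / duration

    if spec.direction == "up":
        x = spec.x_start + speed_mm * t
    else:
        x = x_reach - speed_mm * t
    y_off, z_off = spec.pelvis_offset
    pelvis = np.column_stack([x, np.full(n_frames, y_off), np.full(n_frames, z_off)])
    if spec.step_amplitude > 0:
        # one 180 mm step riser per cycle along the slope
        pelvis[:, 2] += spec.step_amplitude * np.sin(2 * np.pi * x / 180.0)

    grasping = np.zeros(n_frames, dtype=bool)
    for s, e in spec.grasp_episodes:
        grasping |= (frac >= s) & (frac <= e)

    r = scene.rail_radius
    rail_len = scene.rail_length
    side = spec.side
    other = "left" if side == "right" else "right"

    frames: list[SkeletonFrame] = []
    pgp_clean = np.empty((n_frames, 3))
    rng = np.random.default_rng(spec.seed)
    for i in range(n_frames):
        joints: dict[str, np.ndarray] = {"PELVIS": pelvis[i].copy()}
        if grasping[i]:
            base = np.array([float(np.clip(x[i], 0.0, rail_len)), 0.0, 0.0])
            hand = base + np.array([-40.0, 0.0, -r])
            handtip = base + np.array([40.0, 0.0, -r])
            thumb = base + np.array([0.0, 0.6 * r, -0.4 * r])
        else:
            base = pelvis[i] + np.array([-50.0, -80.0, -250.0])
            hand = base + np.array([-30.0, 0.0, 0.0])
            handtip = base + np.array([40.0, 0.0, -10.0])
            thumb = base + np.array([0.0, 15.0, -20.0])
        pgp_clean[i] = (hand + handtip + thumb) / 3.0
        joints[f"HAND_{side.upper()}"] = hand
        joints[f"HANDTIP_{side.upper()}"] = handtip
        joints[f"THUMB_{side.upper()}"] = thumb
        free = pelvis[i] + np.array([-50.0, 120.0, -250.0])
        joints[f"HAND_{other.upper()}"] = free + np.array([-30.0, 0.0, 0.0])
        joints[f"HANDTIP_{other.upper()}"] = free + np.array([40.0, 0.0, -10.0])
        joints[f"THUMB_{other.upper()}"] = free + np.array([0.0, 15.0, -20.0])

        for name in joints:
            q = joints[name]
            if spec.joint_noise_sd > 0:
                q = q + rng.normal(0.0, spec.joint_noise_sd, 3)
            joints[name] = frame.invert(q)
        label = "unlabeled"
        if label_grasps:
            label = "grasped" if grasping[i] else "not_grasped"
        frames.append(SkeletonFrame(timestamp=float(t[i]), joints=joints, grasp_label=label))

    session = Session(
        frames=frames,
        intrinsics=scene.intrinsics,
        participant=participant,
        direction=spec.direction,
        carried="none",
        space="camera",
    )
    truth = TraversalTruth(
        direction=spec.direction,
        speed=spec.speed,
        frame_grasp=grasping,
        pgp_stair=pgp_clean,
        pelvis_stair=pelvis,
        times=t,
        stair_frame=frame,
    )
    return session, truth


def make_labeled_grasp_dataset(
    n_grasp: int,
    n_free: int,
    separation: float = 300.0,
    seed: int = 0,
    cluster_sd: float = 10.0,
    x_range: tuple[float, float] = (1.0, 999.0),
) -> list[GraspSample]:
    """Labeled grasp samples for classifier fixtures.

    Grasped samples cluster at the handrail cross-section center
    ``(Pgp_y, Pgp_z) = (0, 0)`` with isotropic ``cluster_sd``; not-grasped
    samples form an equal-spread cluster offset by ``separation`` (mm, in
    the y-z plane).  Pgp_x is uniform inside the straight segment.
    """
    from .grasp import GraspSample

    rng = np.random.default_rng(seed)
    # offset direction matches where a non-grasping hand sits relative to the
    # rail cross-section in simulated traversals (toward the walker, below)
    offset = separation * np.array([0.41, 0.91])
    samples: list[GraspSample] = []
    for label, n, center in (
        ("grasped", n_grasp, np.zeros(2)),
        ("not_grasped", n_free, offset),
    ):
        yz = rng.normal(0.0, cluster_sd, (n, 2)) + center
        xs = rng.uniform(*x_range, n)
        for i in range(n):
            samples.append(
                GraspSample(
                    timestamp=len(samples) / NOMINAL_FRAME_RATE_HZ,
                    pgp=np.array([xs[i], yz[i, 0], yz[i, 1]]),
                    label=label,
                )
            )
    return samples
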