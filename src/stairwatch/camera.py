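"""Pinhole geometry: depth-pixel back-projection and perspective projection.

The depth camera stores, at pixel ``C = (u, v)``, the metric depth ``Pz`` in
millimetres.  With the intrinsic matrix ``A`` the homogeneous relation
``(u, v, 1)^T * Pz = A p`` links the pixel to its 3-D camera-space point
``p = (X, Y, Z)``; inverting A gives the back-projection, and the forward
direction is the perspective projection used to render heat-map overlays.
Both assume an ideal (pre-rectified) pinhole; integer pixel coordinates
refer to pixel centers.
"""

from __future__ import annotations

import numpy as np

from .recording import CameraIntrinsics, DepthMap


class InvalidDepthError(ValueError):
    """Depth value is zero or negative (sensor dropout or bad input)."""


class BehindCameraError(ValueError):
    """Point has Z <= 0 and cannot be projected."""


class EmptyCloudError(ValueError):
    """A depth-map region contains no valid (nonzero) depth pixels."""


def back_project(pixel, depth: float | np.ndarray, intr: CameraIntrinsics) -> np.ndarray:
    """Back-project depth pixel(s) to camera-space 3-D point(s) in mm.

    Computes ``p = A^-1 (u*Pz, v*Pz, Pz)``, which reduces to
    ``X = (u-cx) Pz / fx``, ``Y = (v-cy) Pz / fy``, ``Z = Pz``.

    Parameters
    ----------
    pixel
        ``(u, v)`` or an (N, 2) array of pixel coordinates.
    depth
        Depth value(s) Pz in millimetres, strictly positive.
    intr
        Camera intrinsics.

    Returns
    -------
    ndarray
        Shape (3,) for one pixel or (N, 3) for a batch.
    """
    pix = np.asarray(pixel, dtype=float)
    z = np.asarray(depth, dtype=float)
    if np.any(z <= 0):
        raise InvalidDepthError("depth must be > 0 mm")
    single = pix.ndim == 1
    pix = np.atleast_2d(pix)
    z = np.broadcast_to(z, pix.shape[:1]).astype(float)
    x = (pix[:, 0] - intr.cx) * z / intr.fx
    y = (pix[:, 1] - intr.cy) * z / intr.fy
    pts = np.column_stack([x, y, z])
    return pts[0] if single else pts


def project(point, intr: CameraIntrinsics) -> np.ndarray:
    """Perspective-project camera-space point(s) (mm) onto the image plane.

    ``u = fx X / Z + cx``, ``v = fy Y / Z + cy``.  Raises
    :class:`BehindCameraError` if any Z <= 0.
    """
    p = np.asarray(point, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    if np.any(p[:, 2] <= 0):
        raise BehindCameraError("cannot project a point with Z <= 0")
    u = intr.fx * p[:, 0] / p[:, 2] + intr.cx
    v = intr.fy * p[:, 1] / p[:, 2] + intr.cy
    uv = np.column_stack([u, v])
    return uv[0] if single else uv


def back_project_region(depth_map: DepthMap, rect: tuple[int, int, int, int]) -> np.ndarray:
    """Back-project every valid pixel of a rectangular depth-map region.

    ``rect = (u0, v0, u1, v1)`` is half-open: pixels with u0 <= u < u1 and
    v0 <= v < v1.  Zero-depth pixels (sensor dropouts) are skipped.  This is
    how the wall-surface point cloud P used for plane fitting is obtained.

    Returns an (N, 3) array of camera-space points in millimetres.
    """
    u0, v0, u1, v1 = (int(x) for x in rect)
    intr = depth_map.intrinsics
    if not (0 <= u0 < u1 <= intr.width and 0 <= v0 < v1 <= intr.height):
        raise ValueError(f"rect {rect} outside image bounds {intr.width}x{intr.height}")
    patch = depth_map.data[v0:v1, u0:u1]
    vv, uu = np.nonzero(patch)
    if vv.size == 0:
        raise EmptyCloudError(f"no valid depth pixels in rect {rect}")
    depths = patch[vv, uu].astype(float)
    pixels = np.column_stack([uu + u0, vv + v0]).astype(float)
    return back_project(pixels, depths, intr)
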