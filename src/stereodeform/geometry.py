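"""Calibrated stereo camera model: rectification, triangulation, projection.

Conventions
-----------
* Pixel coordinates are 0-based ``(column, row)`` sub-pixel floats.
* The 3D reference frame is the **left camera's**: x right, y down, z forward
  (optical axis), in millimeters.
* The right camera is related to the left by ``X_R = R_ext @ X_L + t_ext``.

Rectification follows the standard calibrated construction: a common rotation
aligns both image planes so that the baseline becomes the shared x axis, after
which corresponding points lie on the same image row and depth follows from
disparity as ``Z = f * b / d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .exceptions import BehindCameraError, InvalidGeometryError

__all__ = [
    "CameraRig",
    "RectifiedRig",
    "rectify_pair",
    "triangulate",
    "triangulate_many",
    "project",
    "project_rectified",
]


def _check_intrinsics(K: np.ndarray, name: str) -> None:
    K = np.asarray(K, dtype=float)
    if K.shape != (3, 3):
        raise InvalidGeometryError(f"{name} must be 3x3, got {K.shape}")
    lower = np.tril(K, -1)
    if np.any(np.abs(lower) > 1e-9) or abs(K[2, 2] - 1.0) > 1e-9:
        raise InvalidGeometryError(f"{name} must be upper-triangular with K[2,2]=1")
    if K[0, 0] <= 0 or K[1, 1] <= 0:
        raise InvalidGeometryError(f"{name} focal lengths must be positive")


@dataclass
class CameraRig:
    """Calibrated stereo pair.

    Parameters
    ----------
    K_L, K_R : (3, 3) float arrays
        Intrinsic matrices in pixels.
    dist_L, dist_R : (5,) float arrays
        Radial/tangential distortion ``(k1, k2, p1, p2, k3)``.
    R_ext : (3, 3) float array
        Rotation taking left-camera coordinates to right-camera coordinates.
    t_ext : (3,) float array
        Translation of the same transform, millimeters. ``||t_ext||`` is a
        lower bound on the stereo baseline and must be nonzero.
    image_size : (width, height) in pixels.
    """

    K_L: np.ndarray
    K_R: np.ndarray
    dist_L: np.ndarray
    dist_R: np.ndarray
    R_ext: np.ndarray
    t_ext: np.ndarray
    image_size: tuple[int, int]

    def __post_init__(self) -> None:
        self.K_L = np.asarray(self.K_L, dtype=float)
        self.K_R = np.asarray(self.K_R, dtype=float)
        self.dist_L = np.zeros(5) if self.dist_L is None else np.asarray(self.dist_L, float).ravel()
        self.dist_R = np.zeros(5) if self.dist_R is None else np.asarray(self.dist_R, float).ravel()
        self.R_ext = np.asarray(self.R_ext, dtype=float)
        self.t_ext = np.asarray(self.t_ext, dtype=float).ravel()
        self.image_size = (int(self.image_size[0]), int(self.image_size[1]))
        _check_intrinsics(self.K_L, "K_L")
        _check_intrinsics(self.K_R, "K_R")
        if self.dist_L.size != 5 or self.dist_R.size != 5:
            raise InvalidGeometryError("distortion vectors must have 5 coefficients")
        R = self.R_ext
        if R.shape != (3, 3) or np.linalg.norm(R @ R.T - np.eye(3)) > 1e-6:
            raise InvalidGeometryError("R_ext must be orthonormal")
        if np.linalg.det(R) < 0:
            raise InvalidGeometryError("R_ext must have determinant +1")
        if np.linalg.norm(self.t_ext) <= 1e-12:
            raise InvalidGeometryError("zero baseline: ||t_ext|| must be positive")

    @property
    def baseline(self) -> float:
        """Distance between the two optical centers, mm."""
        return float(np.linalg.norm(self.t_ext))


@dataclass
class RectifiedRig:
    """Result of stereo rectification.

    ``homography_L/R`` map *original* (undistorted) pixels to rectified pixels.
    ``R_rect`` rotates left-camera coordinates into the rectified frame, whose
    origin coincides with the left optical center.
    """

    homography_L: np.ndarray
    homography_R: np.ndarray
    K_rect: np.ndarray
    baseline: float
    R_rect: np.ndarray
    image_size: tuple[int, int]
    epipolar_tolerance: float = 1.5
    rig: CameraRig | None = field(default=None, repr=False)

    @property
    def focal(self) -> float:
        return float(self.K_rect[0, 0])

    @property
    def principal_point(self) -> tuple[float, float]:
        return float(self.K_rect[0, 2]), float(self.K_rect[1, 2])


def _distort(xn: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Apply the 5-coefficient radial-tangential model to normalized coords."""
    k1, k2, p1, p2, k3 = dist
    x, y = xn[..., 0], xn[..., 1]
    r2 = x * x + y * y
    radial = 1.0 + k1 * r2 + k2 * r2 * r2 + k3 * r2 * r2 * r2
    xd = x * radial + 2 * p1 * x * y + p2 * (r2 + 2 * x * x)
    yd = y * radial + p1 * (r2 + 2 * y * y) + 2 * p2 * x * y
    return np.stack([xd, yd], axis=-1)


def _rectifying_rotation(rig: CameraRig) -> np.ndarray:
    """Rotation (left frame -> rectified frame) aligning the baseline with +x."""
    c2 = -rig.R_ext.T @ rig.t_ext  # right optical center, left frame
    b = np.linalg.norm(c2)
    if b <= 1e-12:
        raise InvalidGeometryError("zero baseline")
    r1 = c2 / b
    if r1[0] < 0:  # keep rectified x pointing roughly along image x
        r1 = -r1
    z_old = np.array([0.0, 0.0, 1.0])
    r2 = np.cross(z_old, r1)
    n2 = np.linalg.norm(r2)
    if n2 < 1e-12:
        raise InvalidGeometryError("baseline parallel to optical axis")
    r2 = r2 / n2
    r3 = np.cross(r1, r2)
    return np.stack([r1, r2, r3], axis=0)


def rectify_pair(
    rig: CameraRig,
    img_L: np.ndarray,
    img_R: np.ndarray,
    epipolar_tolerance: float = 1.5,
    interp_order: int = 1,
) -> tuple[RectifiedRig, np.ndarray, np.ndarray]:
    """Resample a stereo pair so that epipolar lines are horizontal rows.

    Returns the rectified rig description plus the two resampled images.
    If the rig is already fronto-parallel and row-aligned (identity relative
    rotation, baseline along x, identical intrinsics, no distortion) the
    homographies reduce to the identity and the images are returned untouched.
    """
    img_L = np.asarray(img_L)
    img_R = np.asarray(img_R)
    w, h = rig.image_size
    for name, im in (("left", img_L), ("right", img_R)):
        if im.shape[1] != w or im.shape[0] != h:
            raise ValueError(f"{name} image shape {im.shape} does not match rig size {(w, h)}")

    R_rect = _rectifying_rotation(rig)
    c2 = -rig.R_ext.T @ rig.t_ext
    baseline = float(np.linalg.norm(c2))

    # Shared rectified intrinsics: average focal, zero skew, average principal point.
    f = 0.25 * (rig.K_L[0, 0] + rig.K_L[1, 1] + rig.K_R[0, 0] + rig.K_R[1, 1])
    cx = 0.5 * (rig.K_L[0, 2] + rig.K_R[0, 2])
    cy = 0.5 * (rig.K_L[1, 2] + rig.K_R[1, 2])
    K_rect = np.array([[f, 0.0, cx], [0.0, f, cy], [0.0, 0.0, 1.0]])

    R_cam = {"L": np.eye(3), "R": rig.R_ext}
    K_cam = {"L": rig.K_L, "R": rig.K_R}
    dist = {"L": rig.dist_L, "R": rig.dist_R}
    H = {s: K_rect @ R_rect @ R_cam[s].T @ np.linalg.inv(K_cam[s]) for s in "LR"}
    for s in "LR":
        H[s] = H[s] / H[s][2, 2]

    out = {}
    for s, img in (("L", img_L), ("R", img_R)):
        identity = np.allclose(H[s], np.eye(3), atol=1e-10) and not np.any(dist[s])
        if identity:
            out[s] = img.copy()
            continue
        cols, rows = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        pix = np.stack([cols, rows, np.ones_like(cols)], axis=-1)
        # rectified pixel -> ray in the source camera frame
        ray = pix @ (R_cam[s] @ R_rect.T @ np.linalg.inv(K_rect)).T
        xn = ray[..., :2] / ray[..., 2:3]
        xd = _distort(xn, dist[s])
        u = K_cam[s][0, 0] * xd[..., 0] + K_cam[s][0, 1] * xd[..., 1] + K_cam[s][0, 2]
        v = K_cam[s][1, 1] * xd[..., 1] + K_cam[s][1, 2]
        if img.ndim == 2:
            out[s] = map_coordinates(img.astype(float), [v, u], order=interp_order, mode="nearest")
        else:
            chans = [
                map_coordinates(img[..., c].astype(float), [v, u], order=interp_order, mode="nearest")
                for c in range(img.shape[2])
            ]
            out[s] = np.stack(chans, axis=-1)
        if np.issubdtype(img.dtype, np.integer):
            out[s] = np.clip(np.round(out[s]), 0, np.iinfo(img.dtype).max).astype(img.dtype)

    rect = RectifiedRig(
        homography_L=H["L"],
        homography_R=H["R"],
        K_rect=K_rect,
        baseline=baseline,
        R_rect=R_rect,
        image_size=rig.image_size,
        epipolar_tolerance=epipolar_tolerance,
        rig=rig,
    )
    return rect, out["L"], out["R"]


def triangulate_many(
    rect: RectifiedRig,
    x_L: np.ndarray,
    x_R: np.ndarray,
    frame: str = "left",
) -> np.ndarray:
    """Triangulate arrays of rectified correspondences.

    ``x_L``, ``x_R`` are (N, 2) arrays of (col, row). Rows are averaged between
    the two views (they agree up to the epipolar tolerance). Returns (N, 3)
    points in mm, in the left-camera frame (default) or the rectified frame.
    """
    x_L = np.atleast_2d(np.asarray(x_L, dtype=float))
    x_R = np.atleast_2d(np.asarray(x_R, dtype=float))
    d = x_L[:, 0] - x_R[:, 0]
    if np.any(d <= 0):
        raise BehindCameraError("non-positive disparity")
    f = rect.focal
    cx, cy = rect.principal_point
    Z = f * rect.baseline / d
    row = 0.5 * (x_L[:, 1] + x_R[:, 1])
    X = (x_L[:, 0] - cx) * Z / f
    Y = (row - cy) * Z / f
    P = np.stack([X, Y, Z], axis=-1)
    if frame == "rectified":
        return P
    if frame == "left":
        return P @ rect.R_rect  # R_rect.T @ P per point
    raise ValueError(f"unknown frame {frame!r}")


def triangulate(rect: RectifiedRig, x_L, x_R, frame: str = "left") -> np.ndarray:
    """Triangulate a single rectified correspondence; see :func:`triangulate_many`."""
    return triangulate_many(rect, np.asarray(x_L)[None, :2], np.asarray(x_R)[None, :2], frame)[0]


def project(rig: CameraRig, S: np.ndarray) -> np.ndarray:
    """Project left-camera-frame 3D points (mm) through K_L (with distortion).

    Implements ``w = K_L @ P`` in homogeneous form. Accepts a single 3-vector
    or an (N, 3) array; returns (col, row) pixels of matching shape.
    """
    S = np.asarray(S, dtype=float)
    single = S.ndim == 1
    P = np.atleast_2d(S)
    if np.any(P[:, 2] <= 0):
        raise BehindCameraError("point has non-positive depth in left camera frame")
    xn = P[:, :2] / P[:, 2:3]
    xd = _distort(xn, rig.dist_L)
    u = rig.K_L[0, 0] * xd[:, 0] + rig.K_L[0, 1] * xd[:, 1] + rig.K_L[0, 2]
    v = rig.K_L[1, 1] * xd[:, 1] + rig.K_L[1, 2]
    out = np.stack([u, v], axis=-1)
    return out[0] if single else out


def project_rectified(rect: RectifiedRig, P: np.ndarray, camera: str = "L") -> np.ndarray:
    """Project left-camera-frame points into the rectified left or right view."""
    P = np.asarray(P, dtype=float)
    single = P.ndim == 1
    pts = np.atleast_2d(P) @ rect.R_rect.T  # into rectified frame
    if camera == "R":
        pts = pts - np.array([rect.baseline, 0.0, 0.0])
    elif camera != "L":
        raise ValueError("camera must be 'L' or 'R'")
    if np.any(pts[:, 2] <= 0):
        raise BehindCameraError("point has non-positive depth in rectified frame")
    f = rect.focal
    cx, cy = rect.principal_point
    u = f * pts[:, 0] / pts[:, 2] + cx
    v = f * pts[:, 1] / pts[:, 2] + cy
    out = np.stack([u, v], axis=-1)
    return out[0] if single else out
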