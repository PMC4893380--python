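"""Ground-truthed synthetic stereo sequences of a deformable textured surface.

The scene is a smooth heightfield (a gently bumpy tissue-like surface about
100 mm below a narrow-baseline stereo rig) carrying band-limited albedo
texture, deformed over time by a Gaussian indentation of scheduled amplitude
and imaged under a Lambertian model with a point light co-located with the
camera. Rendering is by per-pixel ray / heightfield intersection (inverse
mapping), so the returned per-pixel depth and displacement ground truth are
exact up to solver tolerance, and a dark tool rod occludes the indentation
center while it presses.

Everything is deterministic given the seed; the undeformed first frame serves
as the reference structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RectBivariateSpline
from scipy.ndimage import gaussian_filter, spline_filter, map_coordinates

from .exceptions import StereoDeformError
from .force import DEMO_MODEL, DiskRegion, ForceDisplacementModel
from .geometry import CameraRig

__all__ = ["SceneParams", "SyntheticScene", "RenderResult", "make_scene", "render_stereo",
           "ground_truth_force", "gt_correspondences"]

_RANGES = {
    "depth_mm": (80.0, 150.0),
    "baseline_mm": (4.0, 8.0),
    "focal_px": (800.0, 1500.0),
}


@dataclass
class SceneParams:
    """Scene configuration; defaults emulate a surgical-microscope setup."""

    depth_mm: float = 100.0
    baseline_mm: float = 6.0
    focal_px: float = 1200.0
    image_size: tuple[int, int] = (640, 480)
    surface: str = "bumpy"  # or "plane"
    bump_amplitude_mm: float = 1.5
    bump_scale_mm: float = 14.0
    texture_scale_px: float = 2.5
    indent_sigma_mm: float = 6.0
    max_amplitude_mm: float = 10.0
    n_frames: int = 6
    tool_radius_mm: float = 4.0
    include_tool: bool = True
    rig_toe_deg: float = 0.0  # relative rotation about y (verging cameras)
    noise_sigma: float = 0.0  # additive image noise (intensity units, [0,1] scale)

    def validate(self) -> None:
        for name, (lo, hi) in _RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise StereoDeformError(
                    f"{name}={v} outside supported range [{lo}, {hi}]"
                )
        if self.n_frames < 1 or self.max_amplitude_mm < 0 or self.indent_sigma_mm <= 0:
            raise StereoDeformError("invalid schedule parameters")
        if self.surface not in ("bumpy", "plane"):
            raise StereoDeformError(f"unknown surface type {self.surface!r}")


@dataclass
class RenderResult:
    """One rendered stereo frame plus per-pixel ground truth (left camera)."""

    img_L: np.ndarray
    img_R: np.ndarray
    gt_depth_L: np.ndarray  # mm, along the left optical axis
    gt_displacement_L: np.ndarray  # mm, |3D displacement from reference|
    tool_mask_L: np.ndarray  # bool, True where the tool occludes
    amplitude: float  # scheduled indentation amplitude, mm


@dataclass
class SyntheticScene:
    """A fully specified synthetic scene; see :func:`make_scene`."""

    params: SceneParams
    seed: int
    rig: CameraRig
    schedule: np.ndarray  # indentation amplitude per frame, mm
    indent_center: np.ndarray  # (x, y) surface coordinates, mm
    material: ForceDisplacementModel
    _base_spline: RectBivariateSpline = field(repr=False)
    _texture: np.ndarray = field(repr=False)  # cubic-prefiltered albedo grid
    _extent: float = 0.0  # texture/surface half-extent, mm

    # -- surface geometry -------------------------------------------------
    def indentation_depth(self, x, y, frame: int) -> np.ndarray:
        """Vertical indentation displacement (mm) of material point (x, y)."""
        a = float(self.schedule[frame])
        r2 = (np.asarray(x, float) - self.indent_center[0]) ** 2 + (
            np.asarray(y, float) - self.indent_center[1]
        ) ** 2
        return a * np.exp(-r2 / (2.0 * self.params.indent_sigma_mm**2))

    def surface_z(self, x, y, frame: int = 0) -> np.ndarray:
        """Heightfield depth z(x, y) at the given frame, mm (left frame)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = self._base_spline.ev(y.ravel(), x.ravel()).reshape(x.shape)
        return z + self.indentation_depth(x, y, frame)

    def surface_gradient(self, x, y, frame: int = 0) -> tuple[np.ndarray, np.ndarray]:
        """(dz/dx, dz/dy) of the deformed heightfield."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        zx = self._base_spline.ev(y.ravel(), x.ravel(), dy=1).reshape(x.shape)
        zy = self._base_spline.ev(y.ravel(), x.ravel(), dx=1).reshape(x.shape)
        s2 = self.params.indent_sigma_mm**2
        g = self.indentation_depth(x, y, frame)
        zx = zx + g * (-(x - self.indent_center[0]) / s2)
        zy = zy + g * (-(y - self.indent_center[1]) / s2)
        return zx, zy

    def displacement_at(self, points_xy: np.ndarray, frame: int) -> np.ndarray:
        """|3D displacement| (mm) of material points (N, 2) at a frame.

        Material points move purely along +z (away from the camera), so the
        magnitude equals the vertical indentation depth.
        """
        pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
        return self.indentation_depth(pts[:, 0], pts[:, 1], frame)

    def albedo(self, x, y) -> np.ndarray:
        """Band-limited procedural albedo sampled at surface coords (mm)."""
        n = self._texture.shape[0]
        sx = (np.asarray(x, float) + self._extent) / (2 * self._extent) * (n - 1)
        sy = (np.asarray(y, float) + self._extent) / (2 * self._extent) * (n - 1)
        return map_coordinates(
            self._texture, [sy.ravel(), sx.ravel()], order=3, prefilter=False, mode="nearest"
        ).reshape(np.shape(x))

    def tool_region(self) -> DiskRegion:
        """Occluded tool-tip area in surface coordinates (mm)."""
        return DiskRegion(center=self.indent_center, radius=self.params.tool_radius_mm)

    @property
    def n_frames(self) -> int:
        return int(self.schedule.size)


def make_scene(params: SceneParams | None = None, seed: int = 0) -> SyntheticScene:
    """Build a deterministic scene from parameters and a seed."""
    params = params or SceneParams()
    params.validate()
    rng = np.random.default_rng(seed)
    w, h = params.image_size
    f = params.focal_px
    K = np.array([[f, 0.0, (w - 1) / 2.0], [0.0, f, (h - 1) / 2.0], [0.0, 0.0, 1.0]])
    if abs(params.rig_toe_deg) > 0:
        a = np.radians(params.rig_toe_deg)
        R_ext = np.array(
            [[np.cos(a), 0.0, -np.sin(a)], [0.0, 1.0, 0.0], [np.sin(a), 0.0, np.cos(a)]]
        )
    else:
        R_ext = np.eye(3)
    c2 = np.array([params.baseline_mm, 0.0, 0.0])  # right camera center, left frame
    rig = CameraRig(
        K_L=K, K_R=K.copy(), dist_L=np.zeros(5), dist_R=np.zeros(5),
        R_ext=R_ext, t_ext=-R_ext @ c2, image_size=(w, h),
    )

    # lateral extent covering both frusta at max depth, with margin
    zmax = params.depth_mm + params.bump_amplitude_mm + params.max_amplitude_mm + 5.0
    extent = 1.35 * (max(w, h) / 2.0) * zmax / f + params.baseline_mm

    # base heightfield: smooth seeded bumps on a coarse grid, cubic spline
    ngrid = 56
    ax = np.linspace(-extent, extent, ngrid)
    if params.surface == "plane":
        zgrid = np.full((ngrid, ngrid), params.depth_mm)
    else:
        cell_mm = 2 * extent / (ngrid - 1)
        raw = rng.standard_normal((ngrid, ngrid))
        raw = gaussian_filter(raw, params.bump_scale_mm / cell_mm, mode="nearest")
        raw = raw / max(np.abs(raw).max(), 1e-12)
        zgrid = params.depth_mm + params.bump_amplitude_mm * raw
    base = RectBivariateSpline(ax, ax, zgrid, kx=3, ky=3)

    # band-limited texture: smoothed uniform noise, detector-friendly blobs
    ntex = 1024
    tex = rng.uniform(0.0, 1.0, (ntex, ntex))
    tex = gaussian_filter(tex, params.texture_scale_px, mode="wrap")
    tex = (tex - tex.min()) / max(np.ptp(tex), 1e-12)
    tex = 0.25 + 0.70 * tex
    tex = spline_filter(tex, order=3)  # prefilter once for cubic sampling

    jitter = rng.uniform(-3.0, 3.0, size=2)
    schedule = (
        np.linspace(0.0, params.max_amplitude_mm, params.n_frames)
        if params.n_frames > 1
        else np.array([0.0])
    )
    return SyntheticScene(
        params=params,
        seed=seed,
        rig=rig,
        schedule=schedule,
        indent_center=jitter,
        material=DEMO_MODEL,
        _base_spline=base,
        _texture=tex,
        _extent=extent,
    )


def _intersect_rays(scene: SyntheticScene, origin: np.ndarray, dirs: np.ndarray,
                    frame: int, iters: int = 30) -> tuple[np.ndarray, ...]:
    """Fixed-point ray/heightfield intersection. dirs is (..., 3), unit z."""
    dx, dy = dirs[..., 0], dirs[..., 1]
    z = np.full(dx.shape, scene.params.depth_mm)
    for _ in range(iters):
        x = origin[0] + dx * (z - origin[2])
        y = origin[1] + dy * (z - origin[2])
        z_new = scene.surface_z(x, y, frame)
        if np.max(np.abs(z_new - z)) < 1e-10:
            z = z_new
            break
        z = z_new
    x = origin[0] + dx * (z - origin[2])
    y = origin[1] + dy * (z - origin[2])
    return x, y, z


def _shade(scene: SyntheticScene, x, y, z, frame: int) -> np.ndarray:
    """Lambertian shading with a point light at the left camera center."""
    zx, zy = scene.surface_gradient(x, y, frame)
    nrm = np.sqrt(zx * zx + zy * zy + 1.0)
    # normal (zx, zy, -1)/nrm, light direction -P/|P|
    r = np.sqrt(x * x + y * y + z * z)
    cos_t = (z - zx * x - zy * y) / (nrm * r)  # = n . (-P/|P|)
    cos_t = np.clip(cos_t, 0.0, 1.0)
    falloff = (scene.params.depth_mm / r) ** 2
    return scene.albedo(x, y) * cos_t * falloff


def _tool_mask(scene: SyntheticScene, camera: str, frame: int) -> np.ndarray:
    """Rod-shaped occluder mask in image space, tip at the indentation center."""
    w, h = scene.params.image_size
    mask = np.zeros((h, w), dtype=bool)
    if not scene.params.include_tool or scene.schedule[frame] <= 0:
        return mask
    cx, cy = scene.indent_center
    z_tip = scene.surface_z(np.array(cx), np.array(cy), frame)
    P = np.array([cx, cy, float(z_tip)])
    if camera == "R":
        P = scene.rig.R_ext @ P + scene.rig.t_ext
        K = scene.rig.K_R
    else:
        K = scene.rig.K_L
    u = K[0, 0] * P[0] / P[2] + K[0, 2]
    v = K[1, 1] * P[1] / P[2] + K[1, 2]
    radius_px = scene.params.tool_radius_mm * K[0, 0] / P[2]
    cols, rows = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    mask |= (cols - u) ** 2 + (rows - v) ** 2 <= radius_px**2
    mask |= (np.abs(cols - u) <= radius_px) & (rows <= v)  # shaft to image top
    return mask


def render_stereo(scene: SyntheticScene, frame: int) -> RenderResult:
    """Render one stereo frame with exact per-pixel ground truth."""
    if not 0 <= frame < scene.n_frames:
        raise StereoDeformError(f"frame {frame} outside schedule of {scene.n_frames}")
    w, h = scene.params.image_size
    rig = scene.rig
    cols, rows = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))

    # left camera rays from the origin
    dirs_L = np.stack(
        [(cols - rig.K_L[0, 2]) / rig.K_L[0, 0], (rows - rig.K_L[1, 2]) / rig.K_L[1, 1],
         np.ones_like(cols)],
        axis=-1,
    )
    xL, yL, zL = _intersect_rays(scene, np.zeros(3), dirs_L, frame)
    img_L = _shade(scene, xL, yL, zL, frame)

    # right camera: origin and ray directions expressed in the left frame
    c2 = -rig.R_ext.T @ rig.t_ext
    d_cam = np.stack(
        [(cols - rig.K_R[0, 2]) / rig.K_R[0, 0], (rows - rig.K_R[1, 2]) / rig.K_R[1, 1],
         np.ones_like(cols)],
        axis=-1,
    )
    dirs_R = d_cam @ rig.R_ext  # rows: R_ext.T @ d
    dirs_R = dirs_R / dirs_R[..., 2:3]
    xR, yR, zR = _intersect_rays(scene, c2, dirs_R, frame)
    img_R = _shade(scene, xR, yR, zR, frame)

    gt_disp = scene.indentation_depth(xL, yL, frame)
    tool_L = _tool_mask(scene, "L", frame)
    tool_R = _tool_mask(scene, "R", frame)
    rng = np.random.default_rng((scene.seed * 1000003 + frame) % (2**31))
    tool_tex_L = 0.05 + 0.015 * rng.random(img_L.shape)
    tool_tex_R = 0.05 + 0.015 * rng.random(img_R.shape)
    img_L = np.where(tool_L, tool_tex_L, img_L)
    img_R = np.where(tool_R, tool_tex_R, img_R)
    if scene.params.noise_sigma > 0:
        img_L = img_L + rng.normal(0.0, scene.params.noise_sigma, img_L.shape)
        img_R = img_R + rng.normal(0.0, scene.params.noise_sigma, img_R.shape)
    img_L = np.clip(img_L, 0.0, 1.0)
    img_R = np.clip(img_R, 0.0, 1.0)
    return RenderResult(
        img_L=img_L, img_R=img_R, gt_depth_L=zL, gt_displacement_L=gt_disp,
        tool_mask_L=tool_L, amplitude=float(scene.schedule[frame]),
    )


def ground_truth_force(scene: SyntheticScene, frame: int) -> float:
    """Force (N) implied by the material model at the scheduled amplitude."""
    if not 0 <= frame < scene.n_frames:
        raise StereoDeformError(f"frame {frame} outside schedule of {scene.n_frames}")
    return float(scene.material.evaluate(float(scene.schedule[frame])))


def gt_correspondences(
    scene: SyntheticScene, frame: int = 0, n: int = 100, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample ground-truth stereo correspondences.

    Returns (P, x_L, x_R): (n, 3) surface points in the left frame and their
    exact projections (col, row) in both cameras.
    """
    rng = np.random.default_rng(seed)
    rig = scene.rig
    w, h = scene.params.image_size
    half_x = 0.35 * w * scene.params.depth_mm / rig.K_L[0, 0]
    half_y = 0.35 * h * scene.params.depth_mm / rig.K_L[0, 0]
    x = rng.uniform(-half_x, half_x, n)
    y = rng.uniform(-half_y, half_y, n)
    z = scene.surface_z(x, y, frame)
    P = np.stack([x, y, z], axis=-1)
    xL = np.stack(
        [rig.K_L[0, 0] * x / z + rig.K_L[0, 2], rig.K_L[1, 1] * y / z + rig.K_L[1, 2]],
        axis=-1,
    )
    PR = P @ rig.R_ext.T + rig.t_ext
    xR = np.stack(
        [rig.K_R[0, 0] * PR[:, 0] / PR[:, 2] + rig.K_R[0, 2],
         rig.K_R[1, 1] * PR[:, 1] / PR[:, 2] + rig.K_R[1, 2]],
        axis=-1,
    )
    return P, xL, xR


def to_uint8(img: np.ndarray) -> np.ndarray:
    """Quantize a [0, 1] float render to an 8-bit image."""
    return np.clip(np.round(np.asarray(img, float) * 255.0), 0, 255).astype(np.uint8)
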