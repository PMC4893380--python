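"""Temporal tracking, per-point 3D deformation, and 3D thin-plate splines.

Deformation at a surface point is the Euclidean distance between its current
triangulated position and its position in the reference structure,
``D = ||S_t - S_O||`` (mm). Points whose temporal track is reliable are
*stable* and evaluated directly; points that carry 3D data but no trustworthy
track (e.g. propagated matches, or tracks lost under the tool) are *unstable*
and are carried onto the current surface by a 3D thin-plate-spline warp whose
control points are the stable features.

The tracker is a translation-only pyramidal gradient-descent (Lucas-Kanade
style) patch tracker against the frame-0 template, with NCC of the matched
patch as its confidence; confidence below threshold marks the frame lost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import griddata
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.spatial import cKDTree

from .exceptions import DegenerateConfigurationError, StereoDeformError
from .features import FeatureRegion, ncc
from .geometry import RectifiedRig, project_rectified
from .matching import PointCloud

__all__ = [
    "TrackerConfig",
    "TrackedTrajectory",
    "track_features",
    "DeformationField",
    "deformation_at_stable",
    "TPSWarp",
    "fit_tps",
    "map_unstable",
    "render_heatmap",
    "save_heatmap",
]


# ---------------------------------------------------------------------------
# temporal tracking
# ---------------------------------------------------------------------------

@dataclass
class TrackerConfig:
    half_window: int = 7  # 15x15 patch
    pyramid_levels: int = 3
    iterations: int = 8
    confidence_threshold: float = 0.7
    max_step_px: float = 20.0  # per-frame teleport guard


@dataclass
class TrackedTrajectory:
    """One feature's track on the left image plane.

    ``positions`` is (T, 2) in px; ``status`` holds one of
    {"tracked", "lost"} per frame; ``S`` is the per-frame 3D position (mm,
    left frame) filled in by the pipeline when a stereo partner exists, NaN
    otherwise.
    """

    feature_id: int
    positions: np.ndarray
    confidence: np.ndarray
    status: list[str]
    S: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.S is None:
            self.S = np.full((self.positions.shape[0], 3), np.nan)


def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [np.asarray(img, dtype=float)]
    for _ in range(levels - 1):
        pyr.append(gaussian_filter(pyr[-1], 1.0, mode="nearest")[::2, ::2])
    return pyr


def _patch(img: np.ndarray, center: np.ndarray, half: int) -> np.ndarray:
    off = np.arange(-half, half + 1, dtype=float)
    cc, rr = np.meshgrid(center[0] + off, center[1] + off)
    return map_coordinates(img, [rr, cc], order=1, mode="nearest")


def _lk_refine(img: np.ndarray, template: np.ndarray, center: np.ndarray,
               half: int, iterations: int) -> np.ndarray:
    """Translation-only inverse-additive LK step at one pyramid level."""
    pos = center.astype(float).copy()
    for _ in range(iterations):
        cur = _patch(img, pos, half)
        gy, gx = np.gradient(cur)
        err = (cur - template).ravel()
        A = np.stack([gx.ravel(), gy.ravel()], axis=1)
        H = A.T @ A
        if np.linalg.cond(H) > 1e8:
            break
        step = np.linalg.solve(H, A.T @ err)
        pos -= step
        if np.hypot(*step) < 1e-3:
            break
    return pos


def track_features(
    frames,
    initial: list[FeatureRegion],
    config: TrackerConfig | None = None,
) -> list[TrackedTrajectory]:
    """Track features from frame 0 through a left-camera image sequence.

    Each feature's square patch in frame 0 is the fixed template. A frame is
    marked lost when the NCC confidence of the matched patch falls below the
    threshold, when the solution leaves the image, or when the update exceeds
    the per-frame displacement bound (in which case the position is held).
    """
    config = config or TrackerConfig()
    frames = [np.asarray(f, dtype=float) for f in frames]
    if len(frames) == 0:
        raise StereoDeformError("empty image sequence")
    T = len(frames)
    h, w = frames[0].shape[:2]
    levels = config.pyramid_levels
    half = config.half_window
    pyramids = [_pyramid(f, levels) for f in frames]

    trajectories: list[TrackedTrajectory] = []
    for fid, feat in enumerate(initial):
        x0 = np.asarray(feat.x, dtype=float)
        # sliding templates: refreshed at every confidently tracked frame, so
        # gradual geometric distortion of deforming tissue does not starve
        # the confidence score the way a fixed reference patch would
        templates = [
            _patch(pyramids[0][lv], x0 / 2**lv, half) for lv in range(levels)
        ]
        positions = np.zeros((T, 2))
        conf = np.zeros(T)
        status = ["tracked"] * T
        positions[0] = x0
        conf[0] = 1.0
        last_good = x0.copy()
        for t in range(1, T):
            pos = last_good.copy()
            for lv in reversed(range(levels)):
                pos = 2**lv * _lk_refine(
                    pyramids[t][lv], templates[lv], pos / 2**lv, half, config.iterations
                )
            step = np.linalg.norm(pos - last_good)
            inside = half <= pos[0] < w - half and half <= pos[1] < h - half
            if not inside or step > config.max_step_px:
                positions[t] = last_good
                conf[t] = 0.0
                status[t] = "lost"
                continue
            c = ncc(templates[0], _patch(frames[t], pos, half))
            positions[t] = pos
            conf[t] = c
            if c < config.confidence_threshold:
                status[t] = "lost"
            else:
                last_good = pos
                templates = [
                    _patch(pyramids[t][lv], pos / 2**lv, half) for lv in range(levels)
                ]
        trajectories.append(
            TrackedTrajectory(feature_id=fid, positions=positions, confidence=conf, status=status)
        )
    return trajectories


# ---------------------------------------------------------------------------
# deformation field
# ---------------------------------------------------------------------------

@dataclass
class DeformationField:
    """Per-point deformation magnitudes with image locations.

    ``D[i] = ||current[i] - reference[i]||`` in mm for stable points;
    unstable points may carry a TPS-mapped current position instead
    (``stable[i] = False``) with reduced confidence.
    """

    ids: np.ndarray
    w: np.ndarray  # (N, 2) image locations, px
    D: np.ndarray  # (N,) mm
    reference: np.ndarray  # (N, 3) mm
    current: np.ndarray  # (N, 3) mm
    stable: np.ndarray  # (N,) bool
    confidence: np.ndarray  # (N,) in [0, 1]

    def __len__(self) -> int:
        return int(self.D.size)

    @classmethod
    def empty(cls) -> "DeformationField":
        z = np.empty((0,))
        return cls(ids=np.empty((0,), int), w=np.empty((0, 2)), D=z,
                   reference=np.empty((0, 3)), current=np.empty((0, 3)),
                   stable=np.empty((0,), bool), confidence=z)


def deformation_at_stable(
    S_t: np.ndarray,
    S_O: np.ndarray,
    ids_t: np.ndarray | None = None,
    ids_O: np.ndarray | None = None,
    w: np.ndarray | None = None,
) -> DeformationField:
    """Per-point deformation ``D = ||S_t - S_O||`` between corresponding clouds.

    Correspondence is by id; ids present in only one cloud are skipped with a
    warning. With no ids, the clouds must align row-by-row. ``w`` gives image
    locations for the points of ``S_t`` (optional, NaN otherwise).
    """
    S_t = np.atleast_2d(np.asarray(S_t, dtype=float))
    S_O = np.atleast_2d(np.asarray(S_O, dtype=float))
    if ids_t is None and ids_O is None:
        if S_t.shape != S_O.shape:
            raise ValueError("clouds must have equal shape when no ids are given")
        ids_t = ids_O = np.arange(S_t.shape[0])
    ids_t = np.asarray(ids_t)
    ids_O = np.asarray(ids_O)
    common, it, io = np.intersect1d(ids_t, ids_O, return_indices=True)
    skipped = (ids_t.size - common.size) + (ids_O.size - common.size)
    if skipped:
        warnings.warn(f"{skipped} point(s) present in only one cloud were skipped")
    cur, ref = S_t[it], S_O[io]
    D = np.linalg.norm(cur - ref, axis=1)
    w_out = np.asarray(w, float)[it] if w is not None else np.full((common.size, 2), np.nan)
    return DeformationField(
        ids=common, w=w_out, D=D, reference=ref, current=cur,
        stable=np.ones(common.size, dtype=bool), confidence=np.ones(common.size),
    )


# ---------------------------------------------------------------------------
# 3D thin-plate splines
# ---------------------------------------------------------------------------

@dataclass
class TPSWarp:
    """3D thin-plate-spline warp with kernel ``U(r) = r``.

    ``transform`` evaluates ``f(x) = A^T [1, x] + sum_k w_k U(||x - s_k||)``
    per output coordinate; with ``lam = 0`` the warp interpolates its control
    points exactly.
    """

    source: np.ndarray  # (n, 3) control sources
    weights: np.ndarray  # (n, 3) kernel weights
    affine: np.ndarray  # (4, 3): row 0 translation, rows 1..3 linear part
    lam: float = 0.0

    def transform(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        r = np.sqrt(
            np.maximum(
                np.sum((pts[:, None, :] - self.source[None, :, :]) ** 2, axis=2), 0.0
            )
        )
        out = self.affine[0] + pts @ self.affine[1:] + r @ self.weights
        return out if np.asarray(points).ndim > 1 else out[0]


def fit_tps(control_source: np.ndarray, control_target: np.ndarray, lam: float = 0.0) -> TPSWarp:
    """Fit a 3D TPS mapping control sources onto control targets.

    Solves the bordered system ``[[K + lam*I, P], [P^T, 0]]`` with
    ``K_ij = ||s_i - s_j||`` and ``P = [1 | s]``; the side conditions
    (kernel weights orthogonal to the affine monomials) hold by construction.
    Requires at least 4 control points not all coplanar.
    """
    src = np.atleast_2d(np.asarray(control_source, dtype=float))
    dst = np.atleast_2d(np.asarray(control_target, dtype=float))
    n = src.shape[0]
    if src.shape != dst.shape or src.shape[1] != 3:
        raise ValueError("control point arrays must both be (n, 3)")
    if n < 4:
        raise DegenerateConfigurationError("need at least 4 control points")
    if lam < 0:
        raise ValueError("regularization must be non-negative")
    P = np.hstack([np.ones((n, 1)), src])
    if np.linalg.matrix_rank(P, tol=1e-9 * max(1.0, np.abs(src).max())) < 4:
        raise DegenerateConfigurationError("control points are coplanar or degenerate")
    K = np.sqrt(
        np.maximum(np.sum((src[:, None, :] - src[None, :, :]) ** 2, axis=2), 0.0)
    )
    A = np.zeros((n + 4, n + 4))
    A[:n, :n] = K + lam * np.eye(n)
    A[:n, n:] = P
    A[n:, :n] = P.T
    b = np.zeros((n + 4, 3))
    b[:n] = dst
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise DegenerateConfigurationError(f"singular TPS system: {exc}") from exc
    return TPSWarp(source=src, weights=sol[:n], affine=sol[n:], lam=float(lam))


def map_unstable(
    warp: TPSWarp,
    S_unstable: np.ndarray,
    S_reference: np.ndarray,
    cloud_t1: PointCloud,
    rect: RectifiedRig,
    ids: np.ndarray | None = None,
    radius_px: float = 2.0,
    max_deformation_mm: float | None = None,
) -> DeformationField:
    """Carry unstable points onto the current surface and read deformation.

    Each unstable point is mapped by the stable-feature TPS warp and
    projected to the left image at ``w``. If the current reconstruction has
    a point within ``radius_px`` of ``w``, that 3D position (and full
    confidence) is used; otherwise the warped position itself is reported
    with a low-confidence flag. ``S_reference`` holds the points' reference
    positions from which D is measured. Points projecting behind the camera
    are dropped with a warning.
    """
    S_unstable = np.atleast_2d(np.asarray(S_unstable, dtype=float))
    S_reference = np.atleast_2d(np.asarray(S_reference, dtype=float))
    if S_unstable.shape != S_reference.shape:
        raise ValueError("unstable and reference arrays must align")
    n = S_unstable.shape[0]
    ids = np.arange(n) if ids is None else np.asarray(ids)
    mapped = warp.transform(S_unstable) if n else np.empty((0, 3))

    ok = mapped[:, 2] > 0 if n else np.empty((0,), bool)
    if n and not np.all(ok):
        warnings.warn(f"{int(np.sum(~ok))} unstable point(s) projected behind the camera")
    mapped, ref, ids = mapped[ok], S_reference[ok], ids[ok]
    if mapped.shape[0] == 0:
        return DeformationField.empty()
    w = project_rectified(rect, mapped, camera="L")

    current = mapped.copy()
    confident = np.zeros(mapped.shape[0], dtype=bool)
    if len(cloud_t1):
        tree = cKDTree(cloud_t1.left_px)
        dist, idx = tree.query(w, distance_upper_bound=radius_px)
        hit = np.isfinite(dist)
        if max_deformation_mm is not None and np.any(hit):
            # guard against gross mis-association with a different landmark
            cand = cloud_t1.points[np.where(hit, idx, 0)]
            hit &= np.linalg.norm(cand - ref, axis=1) <= max_deformation_mm
        current[hit] = cloud_t1.points[idx[hit]]
        confident = hit
    D = np.linalg.norm(current - ref, axis=1)
    return DeformationField(
        ids=ids, w=w, D=D, reference=ref, current=current,
        stable=np.zeros(ids.size, dtype=bool),
        confidence=np.where(confident, 1.0, 0.5),
    )


def merge_fields(*fields: DeformationField) -> DeformationField:
    """Concatenate deformation fields (e.g. stable + unstable parts)."""
    parts = [f for f in fields if len(f)]
    if not parts:
        return DeformationField.empty()
    return DeformationField(
        ids=np.concatenate([f.ids for f in parts]),
        w=np.vstack([f.w for f in parts]),
        D=np.concatenate([f.D for f in parts]),
        reference=np.vstack([f.reference for f in parts]),
        current=np.vstack([f.current for f in parts]),
        stable=np.concatenate([f.stable for f in parts]),
        confidence=np.concatenate([f.confidence for f in parts]),
    )


# ---------------------------------------------------------------------------
# heatmap rendering
# ---------------------------------------------------------------------------

def render_heatmap(
    field: DeformationField,
    image: np.ndarray,
    cmap: str = "inferno",
    alpha: float = 0.55,
) -> tuple[np.ndarray, float]:
    """Overlay the deformation field on an image as a colormapped heatmap.

    D (mm) is linearly interpolated over the convex hull of the feature
    locations and alpha-blended onto the (grayscale) image; pixels outside
    the hull keep the original intensity. Returns ``(rgb_uint8, vmax)`` where
    ``vmax = max(D)`` is the top of the color scale in mm.
    """
    import matplotlib

    if len(field) == 0:
        raise ValueError("deformation field is empty")
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.max() > 1.5:
        img = img / 255.0
    h, w = img.shape
    vmax = float(field.D.max())
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    good = np.isfinite(field.w).all(axis=1)
    pts = field.w[good]
    vals = field.D[good]
    if pts.shape[0] >= 3:
        interp = griddata(pts, vals, (cols, rows), method="linear")
    else:
        interp = np.full((h, w), np.nan)
    scale = vmax if vmax > 0 else 1.0
    colored = matplotlib.colormaps[cmap](
        np.clip(np.nan_to_num(interp, nan=0.0) / scale, 0, 1)
    )[..., :3]
    base = np.stack([img] * 3, axis=-1)
    inside = np.isfinite(interp)[..., None]
    out = np.where(inside, (1 - alpha) * base + alpha * colored, base)
    return (np.clip(out * 255, 0, 255).astype(np.uint8), vmax)


def save_heatmap(field: DeformationField, image: np.ndarray, path,
                 cmap: str = "inferno") -> float:
    """Write a heatmap overlay PNG with an mm-scaled colorbar legend."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.cm import ScalarMappable
    from matplotlib.colors import Normalize

    rgb, vmax = render_heatmap(field, image, cmap=cmap)
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.imshow(rgb)
    ax.set_axis_off()
    sm = ScalarMappable(norm=Normalize(0.0, vmax if vmax > 0 else 1.0), cmap=cmap)
    cbar = fig.colorbar(sm, ax=ax, fraction=0.046)
    cbar.set_label(f"deformation (mm), max {vmax:.2f}")
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
    return vmax
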