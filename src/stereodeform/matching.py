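"""Quasi-dense stereo correspondence on rectified pairs.

Matching proceeds in three stages:

1. **Global matching** — every left region is compared against right regions
   in its epipolar band with the combined similarity
   ``M = IoU(R_i, R_j) + min(c_i, c_j) / max(c_i, c_j)``; a correspondence is
   the argmax of M subject to region overlap above ``thr_r`` and
   histogram-equalized NCC above ``thr_s``, with left-right uniqueness.
2. **Local densification** — additional regions are detected inside the areas
   delimited by the matched ellipses and matched under the same constraints.
3. **Affine propagation** — unmatched left regions lying inside a seed's
   ellipse, with a surface normal within a small cone of the seed's, are
   transferred to the right image through the seed's region-normalizing
   affine maps; a low appearance score at the predicted location rejects the
   transfer as an outlier.

Matched features are triangulated (after 1-D subpixel disparity refinement)
into a quasi-dense point cloud in the left camera frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .exceptions import InvalidFeatureError
from .features import (
    DetectorParams,
    FeatureRegion,
    _sqrtm_spd,
    _to_gray,
    appearance_similarity,
    detect_regions,
    ellipse_overlap,
    extract_patch,
    ncc,
)
from .geometry import RectifiedRig, triangulate_many

__all__ = [
    "MatchConfig",
    "StereoMatch",
    "SurfaceNormalMap",
    "PointCloud",
    "similarity_score",
    "match_global",
    "densify_local",
    "normal_from_pq",
    "estimate_normals",
    "propagate_matches",
    "refine_disparity",
    "reconstruct",
]


@dataclass
class MatchConfig:
    """Thresholds of the constrained matching stage.

    thr_r : minimum elliptical-region overlap (IoU) for a candidate pair.
    thr_s : minimum histogram-equalized NCC (appearance similarity).
    epipolar_tolerance : half-width of the epipolar band, px.
    normal_gate_deg : maximum normal disagreement for propagation, degrees.
    propagation_threshold : minimum appearance score at a propagated location.
    """

    thr_r: float = 0.60
    thr_s: float = 0.90
    epipolar_tolerance: float = 1.5
    normal_gate_deg: float = 1.0
    propagation_threshold: float = 0.80

    def __post_init__(self) -> None:
        for name in ("thr_r", "thr_s", "propagation_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.normal_gate_deg <= 0:
            raise ValueError("normal_gate_deg must be positive")
        if self.epipolar_tolerance <= 0:
            raise ValueError("epipolar_tolerance must be positive")


@dataclass
class StereoMatch:
    """A left/right region pair with its similarity and appearance scores."""

    left: FeatureRegion
    right: FeatureRegion
    M: float
    A: float
    stage: str = "global"  # one of {global, local, propagated}

    @property
    def disparity(self) -> float:
        return float(self.left.x[0] - self.right.x[0])


def similarity_score(f_i: FeatureRegion, f_j: FeatureRegion, recenter: bool = False) -> float:
    """Combined region similarity ``M = IoU + min(c_i,c_j)/max(c_i,c_j)``.

    With ``recenter=True`` the second region is translated onto the first
    region's center before the overlap is computed, so the term compares
    region *shapes* irrespective of disparity.
    """
    if f_i.c <= 0 or f_j.c <= 0:
        raise InvalidFeatureError("saliency strengths must be positive")
    center_j = f_i.x if recenter else f_j.x
    iou = ellipse_overlap((f_i.x, f_i.shape), (center_j, f_j.shape))
    return iou + min(f_i.c, f_j.c) / max(f_i.c, f_j.c)


def _pair_scores(f_i: FeatureRegion, f_j: FeatureRegion, config: MatchConfig):
    """(M, IoU, A) for a candidate pair, or None if a constraint fails.

    The appearance score is evaluated first because it is much cheaper than
    the polygonal ellipse overlap.
    """
    A = appearance_similarity(f_i.patch, f_j.patch)
    if A <= config.thr_s:
        return None
    iou = ellipse_overlap((f_i.x, f_i.shape), (f_i.x, f_j.shape))
    if iou <= config.thr_r:
        return None
    M = iou + min(f_i.c, f_j.c) / max(f_i.c, f_j.c)
    return M, iou, A


def _canonical(features: list[FeatureRegion]) -> list[FeatureRegion]:
    """Order-invariant canonical ordering by (row, col, -c)."""
    return sorted(features, key=lambda f: (f.x[1], f.x[0], -f.c))


def match_global(
    features_L: list[FeatureRegion],
    features_R: list[FeatureRegion],
    config: MatchConfig | None = None,
    stage: str = "global",
) -> list[StereoMatch]:
    """Constrained argmax matching of left regions to right regions.

    For each left region, candidates are right regions within the epipolar
    band whose recentered overlap exceeds ``thr_r`` and appearance similarity
    exceeds ``thr_s``; the candidate with the highest combined similarity M
    wins. Ties break on higher A, then smaller absolute disparity. A right
    region is kept by at most one left region (highest M wins, same
    tie-break), making the output independent of input ordering.
    """
    config = config or MatchConfig()
    feats_L = _canonical(features_L)
    feats_R = _canonical(features_R)
    if not feats_L or not feats_R:
        return []
    rows_R = np.array([f.x[1] for f in feats_R])

    proposals: list[tuple] = []
    for li, f_i in enumerate(feats_L):
        lo = np.searchsorted(rows_R, f_i.x[1] - config.epipolar_tolerance, side="left")
        hi = np.searchsorted(rows_R, f_i.x[1] + config.epipolar_tolerance, side="right")
        best = None
        for rj in range(int(lo), int(hi)):
            scores = _pair_scores(f_i, feats_R[rj], config)
            if scores is None:
                continue
            M, iou, A = scores
            key = (M, A, -abs(f_i.x[0] - feats_R[rj].x[0]))
            if best is None or key > best[0]:
                best = (key, rj, M, A)
        if best is not None:
            proposals.append((best[1], best[0], li, best[2], best[3]))

    # left-right uniqueness: keep the strongest proposal per right region
    chosen: dict[int, tuple] = {}
    for rj, key, li, M, A in proposals:
        incumbent = chosen.get(rj)
        # final tie-break on left position keeps the result deterministic
        full_key = key + (-feats_L[li].x[1], -feats_L[li].x[0])
        if incumbent is None or full_key > incumbent[0]:
            chosen[rj] = (full_key, li, M, A)
    out = [
        StereoMatch(left=feats_L[li], right=feats_R[rj], M=M, A=A, stage=stage)
        for rj, (_, li, M, A) in chosen.items()
    ]
    out.sort(key=lambda m: (m.left.x[1], m.left.x[0]))
    return out


def _too_close(x: np.ndarray, existing: np.ndarray, min_sep: float) -> bool:
    if existing.size == 0:
        return False
    return bool(np.min(np.sum((existing - x) ** 2, axis=1)) < min_sep**2)


def densify_local(
    matches: list[StereoMatch],
    img_L: np.ndarray,
    img_R: np.ndarray,
    config: MatchConfig | None = None,
    detector_params: DetectorParams | None = None,
    inflate: float = 3.0,
) -> list[StereoMatch]:
    """Densify matches by detecting and matching inside the seed regions.

    New regions are detected (at a more permissive threshold) within the
    areas delimited by the matched ellipses, inflated by ``inflate``; they
    are matched under the same constraints as the global stage and appended
    with ``stage='local'``. The output is a superset of the input.
    """
    config = config or MatchConfig()
    if not matches:
        return list(matches)
    base = detector_params or DetectorParams()
    dense = replace(
        base,
        threshold_rel=base.threshold_rel / 4.0,
        min_separation=max(2.0, base.min_separation / 2.0),
        max_features=base.max_features * 2,
    )

    def roi_mask(shape, regions):
        mask = np.zeros(shape, dtype=bool)
        for reg in regions:
            r_ax = inflate * np.sqrt(np.linalg.eigvalsh(reg.shape)[1])
            c0, r0 = reg.x
            rs = slice(max(0, int(r0 - r_ax)), min(shape[0], int(r0 + r_ax) + 1))
            cs = slice(max(0, int(c0 - r_ax)), min(shape[1], int(c0 + r_ax) + 1))
            mask[rs, cs] = True
        return mask

    gL, gR = _to_gray(img_L), _to_gray(img_R)
    mask_L = roi_mask(gL.shape, [m.left for m in matches])
    mask_R = roi_mask(gR.shape, [m.right for m in matches])

    new_L, new_R = [], []
    used_L = np.array([m.left.x for m in matches])
    used_R = np.array([m.right.x for m in matches])
    sep = dense.min_separation
    for f in detect_regions(gL, dense):
        ci, ri = int(round(f.x[0])), int(round(f.x[1]))
        if mask_L[min(ri, gL.shape[0] - 1), min(ci, gL.shape[1] - 1)] and not _too_close(
            f.x, used_L, sep
        ):
            new_L.append(f)
    for f in detect_regions(gR, dense):
        ci, ri = int(round(f.x[0])), int(round(f.x[1]))
        if mask_R[min(ri, gR.shape[0] - 1), min(ci, gR.shape[1] - 1)] and not _too_close(
            f.x, used_R, sep
        ):
            new_R.append(f)

    added = match_global(new_L, new_R, config, stage="local")
    return list(matches) + added


def normal_from_pq(p, q) -> np.ndarray:
    """Unit surface normal from directional gradients:
    ``N = (p, q, -1) / sqrt(p^2 + q^2 + 1)``."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    denom = np.sqrt(p * p + q * q + 1.0)
    return np.stack([p / denom, q / denom, -1.0 / denom], axis=-1)


@dataclass
class SurfaceNormalMap:
    """Per-pixel surface gradients (p, q) and unit normals."""

    p: np.ndarray
    q: np.ndarray
    normals: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        self.normals = normal_from_pq(self.p, self.q)

    def normal_at(self, x) -> np.ndarray:
        """Unit normal at a sub-pixel (col, row) location."""
        col, row = float(x[0]), float(x[1])
        p = float(map_coordinates(self.p, [[row], [col]], order=1, mode="nearest")[0])
        q = float(map_coordinates(self.q, [[row], [col]], order=1, mode="nearest")[0])
        return normal_from_pq(p, q)


@dataclass
class LightModel:
    """Co-located point-light irradiance model used for normal estimation.

    The light sits at the camera center, so image irradiance of a Lambertian
    surface is ``rho * cos(theta) / r^2`` with theta the angle between the
    surface normal and the viewing ray. ``focal/cx/cy`` (px) describe the
    camera so the purely geometric off-axis falloff ``cos^3(alpha)`` can be
    compensated; leave ``focal`` at 0 to skip the compensation.
    """

    focal: float = 0.0
    cx: float = 0.0
    cy: float = 0.0
    smoothing_sigma: float = 12.0
    ref_percentile: float = 98.0
    #: log-brightness deficits below this are attributed to residual albedo
    #: texture and read as flat; tilts much shallower than ~30 deg are
    #: invisible, which suffices for gating propagation across the strong
    #: shading of an indentation flank
    deadband: float = 0.15


def estimate_normals(image: np.ndarray, light_model: LightModel | None = None) -> SurfaceNormalMap:
    """Estimate a smooth surface-normal field from shading.

    The image is smoothed to suppress albedo texture and compensated for the
    known off-axis falloff of a camera-co-located light. The remaining
    *log*-brightness deficit against the brightest (fronto-parallel) surface
    patches is attributed to surface tilt, ``cos(theta) = exp(-deficit)``,
    giving the tilt magnitude ``|(p, q)| = sqrt(1 / cos^2 - 1)`` oriented
    along the descending brightness direction. Deficits inside
    ``light_model.deadband`` are residual texture and read as flat: the
    estimator sees the strong shading of an indentation flank but is blind
    to tilts shallower than roughly 16 degrees. It is a smooth gating field
    for match propagation, not a full shape-from-shading reconstruction.
    """
    lm = light_model or LightModel()
    g = _to_gray(image).astype(float)
    if np.ptp(g) > 1e-12:
        g = (g - g.min()) / np.ptp(g)
    J = gaussian_filter(g, lm.smoothing_sigma, mode="nearest")
    if lm.focal > 0:
        h, w = J.shape
        cols, rows = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        cos_a = lm.focal / np.sqrt(
            lm.focal**2 + (cols - lm.cx) ** 2 + (rows - lm.cy) ** 2
        )
        J = J / cos_a**3
    if np.all(J <= 1e-12):
        zeros = np.zeros_like(J)
        return SurfaceNormalMap(p=zeros, q=zeros)
    L = np.log(np.maximum(J, 1e-12))
    ref = np.percentile(L, lm.ref_percentile)
    deficit = np.clip(ref - L - lm.deadband, 0.0, 3.0)
    cos_t = np.exp(-deficit)
    gmag = np.sqrt(np.maximum(1.0 / cos_t**2 - 1.0, 0.0))
    dLr, dLc = np.gradient(L)
    grad_norm = np.hypot(dLc, dLr)
    safe = np.maximum(grad_norm, 1e-12)
    # tilt points along descending brightness; flat where the field is flat
    p = np.where(grad_norm > 1e-9, -gmag * dLc / safe, 0.0)
    q = np.where(grad_norm > 1e-9, -gmag * dLr / safe, 0.0)
    return SurfaceNormalMap(p=p, q=q)


def _angle_deg(n1: np.ndarray, n2: np.ndarray) -> float:
    c = float(np.clip(np.dot(n1, n2), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def propagate_matches(
    seeds: list[StereoMatch],
    candidates: list[FeatureRegion],
    normals: SurfaceNormalMap | None,
    config: MatchConfig | None = None,
    img_R: np.ndarray | None = None,
) -> list[StereoMatch]:
    """Transfer unmatched left regions to the right image via seed affinity.

    A candidate is propagated from the seed (strongest first) whose left
    ellipse contains the candidate's center and whose surface normal agrees
    within ``normal_gate_deg``. Writing ``M_L`` and ``M_R`` for the affine
    maps normalizing the seed's left/right ellipses to unit circles, the
    predicted right-image location is

        ``f_R = T (f_L - seed_L) + seed_R``,   ``T = M_R^{-1} M_L``,

    (the relative orientation between the normalized regions is identity for
    the small-baseline rectified pairs targeted here). If ``img_R`` is given,
    the appearance at the predicted location must reach
    ``propagation_threshold`` or the transfer is rejected as an outlier.
    """
    config = config or MatchConfig()
    if not seeds:
        return []
    seeds_sorted = sorted(seeds, key=lambda m: (-m.M, m.left.x[1], m.left.x[0]))
    inv_shapes = []
    for s in seeds_sorted:
        try:
            inv_shapes.append(np.linalg.inv(s.left.shape))
        except np.linalg.LinAlgError:
            inv_shapes.append(None)
    seed_normals = [
        normals.normal_at(s.left.x) if normals is not None else None for s in seeds_sorted
    ]
    gR = _to_gray(img_R) if img_R is not None else None

    out: list[StereoMatch] = []
    for cand in _canonical(candidates):
        placed = False
        cand_normal = normals.normal_at(cand.x) if normals is not None else None
        for s, S_inv, n_seed in zip(seeds_sorted, inv_shapes, seed_normals):
            if S_inv is None:
                continue
            d = cand.x - s.left.x
            if float(d @ S_inv @ d) > 1.0:
                continue  # candidate not inside the seed region
            if (
                normals is not None
                and _angle_deg(cand_normal, n_seed) >= config.normal_gate_deg
            ):
                continue
            try:
                M_L_inv = _sqrtm_spd(s.left.shape)  # = M_L^{-1}
                M_R_inv = _sqrtm_spd(s.right.shape)
                T = M_R_inv @ np.linalg.inv(M_L_inv)
            except np.linalg.LinAlgError:
                warnings.warn("singular normalizing transform; candidate skipped")
                continue
            pred = T @ d + s.right.x
            if abs(pred[1] - cand.x[1]) > config.epipolar_tolerance:
                continue
            shape_R = T @ cand.shape @ T.T
            shape_R = 0.5 * (shape_R + shape_R.T)
            if gR is not None:
                if not (0 <= pred[0] < gR.shape[1] and 0 <= pred[1] < gR.shape[0]):
                    continue
                patch_R = extract_patch(gR, pred, shape_R)
                A = appearance_similarity(cand.patch, patch_R)
                if A < config.propagation_threshold:
                    continue
            else:
                patch_R, A = None, float("nan")
            right = FeatureRegion(x=pred, c=cand.c, shape=shape_R, patch=patch_R)
            iou = ellipse_overlap((cand.x, cand.shape), (cand.x, shape_R))
            out.append(
                StereoMatch(left=cand, right=right, M=iou + 1.0, A=A, stage="propagated")
            )
            placed = True
            break
        if not placed:
            continue
    return out


@dataclass
class PointCloud:
    """Triangulated quasi-dense structure in the left-camera frame (mm)."""

    points: np.ndarray  # (N, 3)
    left_px: np.ndarray  # (N, 2) rectified left pixels
    right_px: np.ndarray  # (N, 2)
    stages: np.ndarray  # (N,) str
    ids: np.ndarray  # (N,) int

    def __len__(self) -> int:
        return int(self.points.shape[0])

    @classmethod
    def empty(cls) -> "PointCloud":
        return cls(
            points=np.empty((0, 3)),
            left_px=np.empty((0, 2)),
            right_px=np.empty((0, 2)),
            stages=np.empty((0,), dtype=object),
            ids=np.empty((0,), dtype=int),
        )


def _square_patch(g: np.ndarray, center: np.ndarray, half: int = 5) -> np.ndarray:
    off = np.arange(-half, half + 1, dtype=float)
    cc, rr = np.meshgrid(center[0] + off, center[1] + off)
    return map_coordinates(g, [rr, cc], order=1, mode="nearest")


def refine_disparity(
    matches: list[StereoMatch],
    img_L: np.ndarray,
    img_R: np.ndarray,
    search_px: float = 2.0,
    step: float = 0.25,
    min_ncc: float = 0.5,
) -> list[StereoMatch]:
    """Subpixel 1-D refinement of each match's right-image column.

    The left patch is correlated against the right image along the epipolar
    row around the matched column; a parabola through the NCC peak gives a
    subpixel disparity correction. Matches whose best correlation falls
    below ``min_ncc`` are kept unrefined.
    """
    gL, gR = _to_gray(img_L), _to_gray(img_R)
    offs = np.arange(-search_px, search_px + step / 2, step)
    out = []
    for m in matches:
        tpl = _square_patch(gL, m.left.x)
        row = m.left.x[1]
        scores = np.array(
            [ncc(tpl, _square_patch(gR, np.array([m.right.x[0] + o, row]))) for o in offs]
        )
        k = int(np.argmax(scores))
        if scores[k] < min_ncc:
            out.append(m)
            continue
        delta = offs[k]
        if 0 < k < len(offs) - 1:
            den = scores[k + 1] - 2 * scores[k] + scores[k - 1]
            if den < -1e-12:
                delta += float(
                    np.clip(-0.5 * (scores[k + 1] - scores[k - 1]) / den, -step, step)
                )
        right = FeatureRegion(
            x=np.array([m.right.x[0] + delta, row]),
            c=m.right.c,
            shape=m.right.shape,
            patch=m.right.patch,
        )
        out.append(StereoMatch(left=m.left, right=right, M=m.M, A=m.A, stage=m.stage))
    return out


def filter_cloud_outliers(cloud: PointCloud, k: int = 8, tol_mm: float = 2.5) -> PointCloud:
    """Reject triangulated points inconsistent with their spatial neighborhood.

    The observed surface is smooth at the quasi-dense sampling density, so a
    point whose depth deviates from the median depth of its nearest image
    neighbors by more than ``tol_mm`` is a residual mismatch and is dropped.
    """
    from scipy.spatial import cKDTree

    n = len(cloud)
    if n <= k + 1:
        return cloud
    tree = cKDTree(cloud.left_px)
    _, idx = tree.query(cloud.left_px, k=k + 1)
    med = np.median(cloud.points[idx[:, 1:], 2], axis=1)
    keep = np.abs(cloud.points[:, 2] - med) <= tol_mm
    return PointCloud(
        points=cloud.points[keep], left_px=cloud.left_px[keep],
        right_px=cloud.right_px[keep], stages=cloud.stages[keep],
        ids=cloud.ids[keep],
    )


def reconstruct(
    matches: list[StereoMatch],
    rect: RectifiedRig,
    img_L: np.ndarray | None = None,
    img_R: np.ndarray | None = None,
    refine: bool = True,
) -> PointCloud:
    """Triangulate matches into a quasi-dense point cloud (left frame, mm).

    Non-positive-disparity matches are rejected (behind the camera); the
    returned cloud carries per-point stage provenance, so its size equals
    the match count minus those rejections.
    """
    if not matches:
        return PointCloud.empty()
    if refine and img_L is not None and img_R is not None:
        matches = refine_disparity(matches, img_L, img_R)
    xL = np.array([m.left.x for m in matches])
    xR = np.array([m.right.x for m in matches])
    keep = xL[:, 0] - xR[:, 0] > 0
    if not np.any(keep):
        return PointCloud.empty()
    pts = triangulate_many(rect, xL[keep], xR[keep], frame="left")
    stages = np.array([m.stage for m in matches], dtype=object)[keep]
    ids = np.nonzero(keep)[0]
    return PointCloud(points=pts, left_px=xL[keep], right_px=xR[keep], stages=stages, ids=ids)
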