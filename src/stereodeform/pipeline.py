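"""End-to-end orchestration: stereo reconstruction, temporal deformation
recovery, and force readout.

The per-frame deformation pipeline mirrors the intended intraoperative use:
the undeformed reference frame is reconstructed quasi-densely; distinctive
(global/local) matches are tracked on the left image plane and re-matched in
the right image each frame to triangulate their current positions; their
displacements against the reference give the stable deformation estimates
and serve as TPS control points that carry the remaining (unstable) points
onto the current surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .deformation import (
    DeformationField,
    TrackerConfig,
    deformation_at_stable,
    fit_tps,
    map_unstable,
    merge_fields,
    track_features,
)
from .exceptions import DegenerateConfigurationError, StereoDeformError
from .features import DetectorParams, FeatureRegion, detect_regions, ncc
from .force import (
    DiskRegion,
    ForceDisplacementModel,
    ForceEstimate,
    GaussianIndentation,
    estimate_force,
    fit_indentation,
)
from .geometry import CameraRig, RectifiedRig, rectify_pair, triangulate_many
from .matching import (
    LightModel,
    MatchConfig,
    PointCloud,
    SurfaceNormalMap,
    densify_local,
    estimate_normals,
    filter_cloud_outliers,
    match_global,
    propagate_matches,
    reconstruct,
)
from .matching import _square_patch  # shared patch sampler

__all__ = [
    "StereoResult",
    "reconstruct_pair",
    "DeformationSequence",
    "track_and_deform",
    "force_from_deformation",
]


@dataclass
class StereoResult:
    """Quasi-dense reconstruction of one rectified stereo pair."""

    rect: RectifiedRig
    img_L: np.ndarray
    img_R: np.ndarray
    features_L: list
    features_R: list
    matches: list
    normals: SurfaceNormalMap
    cloud: PointCloud

    @property
    def stage_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in self.matches:
            counts[m.stage] = counts.get(m.stage, 0) + 1
        return counts


def reconstruct_pair(
    rig: CameraRig,
    img_L: np.ndarray,
    img_R: np.ndarray,
    match_config: MatchConfig | None = None,
    detector_params: DetectorParams | None = None,
    densify: bool = True,
    propagate: bool = True,
    refine: bool = True,
    reject_outliers: bool = True,
) -> StereoResult:
    """Run the full quasi-dense stereo stage on one calibrated pair."""
    config = match_config or MatchConfig()
    dparams = detector_params or DetectorParams()
    rect, rL, rR = rectify_pair(rig, img_L, img_R, epipolar_tolerance=config.epipolar_tolerance)

    feats_L = detect_regions(rL, dparams)
    feats_R = detect_regions(rR, dparams)
    matches = match_global(feats_L, feats_R, config)
    if densify and matches:
        matches = densify_local(matches, rL, rR, config, dparams)

    light = LightModel(
        focal=rect.focal, cx=rect.principal_point[0], cy=rect.principal_point[1]
    )
    normals = estimate_normals(rL, light)

    if propagate and matches:
        matched_left = {id(m.left) for m in matches}
        candidates = [f for f in feats_L if id(f) not in matched_left]
        matches = matches + propagate_matches(matches, candidates, normals, config, img_R=rR)

    cloud = reconstruct(matches, rect, rL, rR, refine=refine)
    if reject_outliers:
        cloud = filter_cloud_outliers(cloud)
    return StereoResult(
        rect=rect, img_L=rL, img_R=rR, features_L=feats_L, features_R=feats_R,
        matches=matches, normals=normals, cloud=cloud,
    )


def _stereo_search(
    gL: np.ndarray, gR: np.ndarray, pos: np.ndarray, disparity0: float,
    search_px: float = 4.0, step: float = 0.5, half: int = 8,
) -> tuple[float, float]:
    """1-D NCC search for the right-image column of a left feature.

    A coarse pass locates the peak; a fine pass (step/4) plus a parabola fit
    suppresses the pixel-locking bias of the sampling grid. Returns
    (disparity, confidence).
    """
    tpl = _square_patch(gL, pos, half=half)
    col0 = pos[0] - disparity0

    def sweep(center: float, offsets: np.ndarray) -> np.ndarray:
        return np.array(
            [
                ncc(tpl, _square_patch(gR, np.array([center + o, pos[1]]), half=half))
                for o in offsets
            ]
        )

    coarse_offs = np.arange(-search_px, search_px + step / 2, step)
    coarse = sweep(col0, coarse_offs)
    k = int(np.argmax(coarse))
    best = coarse_offs[k]

    fine_step = step / 4.0
    fine_offs = np.arange(-step, step + fine_step / 2, fine_step)
    fine = sweep(col0 + best, fine_offs)
    j = int(np.argmax(fine))
    delta = best + fine_offs[j]
    if 0 < j < len(fine_offs) - 1:
        den = fine[j + 1] - 2 * fine[j] + fine[j - 1]
        if den < -1e-12:
            delta += float(
                np.clip(-0.5 * (fine[j + 1] - fine[j - 1]) / den, -fine_step, fine_step)
            )
    return float(disparity0 - delta), float(fine[j])


def _demote_inconsistent(
    pos: np.ndarray, D: np.ndarray, k: int = 8, tol_mm: float = 2.0
) -> np.ndarray:
    """Flag stable points whose D disagrees with their spatial neighborhood.

    Tissue deformation is locally smooth, so a point whose displacement
    magnitude deviates from the median of its nearest neighbors by more than
    ``tol_mm`` is almost certainly a wrong stereo re-match; it is demoted to
    the unstable set rather than reported as a stable measurement.
    """
    from scipy.spatial import cKDTree

    n = D.size
    if n <= k + 1:
        return np.zeros(n, dtype=bool)
    tree = cKDTree(pos)
    _, idx = tree.query(pos, k=k + 1)
    med = np.median(D[idx[:, 1:]], axis=1)
    return np.abs(D - med) > tol_mm


def _select_controls(
    src: np.ndarray, dst: np.ndarray, max_n: int = 400, min_sep_mm: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Thin TPS control points to a well-separated subset.

    Near-duplicate controls make the bordered TPS system ill-conditioned;
    a greedy minimum-separation pass over a deterministically shuffled order
    keeps the warp well-posed, spatially spread, and cheap.
    """
    order = np.random.default_rng(0).permutation(src.shape[0])
    keep: list[int] = []
    kept = np.empty((0, 3))
    for i in order:
        if kept.size and np.min(np.sum((kept - src[i]) ** 2, axis=1)) < min_sep_mm**2:
            continue
        keep.append(i)
        kept = np.vstack([kept, src[i]])
        if len(keep) >= max_n:
            break
    return src[keep], dst[keep]


@dataclass
class DeformationSequence:
    """Per-frame deformation fields for a tracked stereo sequence."""

    fields: list[DeformationField]
    reference: StereoResult
    trajectories: list
    stable_ids: np.ndarray = field(default=None)
    reference_frame: int = 0


def track_and_deform(
    rig: CameraRig,
    frames_L,
    frames_R,
    match_config: MatchConfig | None = None,
    detector_params: DetectorParams | None = None,
    tracker_config: TrackerConfig | None = None,
    reference_frame: int = 0,
    tps_lambda: float = 1e-6,
    radius_px: float = 3.0,
    stereo_confidence: float = 0.7,
    max_deformation_mm: float = 25.0,
) -> DeformationSequence:
    """Recover per-frame deformation fields for a calibrated stereo sequence.

    Frames are (left, right) image lists of equal length; ``reference_frame``
    selects the undeformed reference structure S^O (first frame by default).
    """
    if len(frames_L) == 0 or len(frames_L) != len(frames_R):
        raise StereoDeformError("need equal-length nonempty left/right sequences")
    T = len(frames_L)
    if not 0 <= reference_frame < T:
        raise StereoDeformError("reference frame outside sequence")
    config = match_config or MatchConfig()
    tcfg = tracker_config or TrackerConfig()

    ref = reconstruct_pair(
        rig, frames_L[reference_frame], frames_R[reference_frame],
        match_config=config, detector_params=detector_params,
    )
    cloud0 = ref.cloud
    if len(cloud0) == 0:
        raise StereoDeformError("reference reconstruction is empty")
    stages = np.asarray(cloud0.stages)
    stable_sel = np.nonzero((stages == "global") | (stages == "local"))[0]
    unstable_sel = np.nonzero(stages == "propagated")[0]

    # rectify all frames with the reference homographies
    rect_frames_L, rect_frames_R = [], []
    for t in range(T):
        _, rL, rR = rectify_pair(rig, frames_L[t], frames_R[t],
                                 epipolar_tolerance=config.epipolar_tolerance)
        rect_frames_L.append(rL)
        rect_frames_R.append(rR)

    track_feats = [
        FeatureRegion(x=cloud0.left_px[i], c=1.0, shape=25.0 * np.eye(2))
        for i in stable_sel
    ]
    trajectories = track_features(rect_frames_L, track_feats, tcfg)
    disparity_prev = (cloud0.left_px[stable_sel, 0] - cloud0.right_px[stable_sel, 0]).copy()

    # Re-measure the stable reference disparities with the same correlation
    # operator used at later frames, so per-feature texture-induced disparity
    # bias largely cancels in D = ||S_t - S_O||.
    ref_points = cloud0.points.copy()
    gL0, gR0 = rect_frames_L[reference_frame], rect_frames_R[reference_frame]
    for k, i in enumerate(stable_sel):
        pos0 = cloud0.left_px[i]
        d0, conf0 = _stereo_search(gL0, gR0, pos0, disparity_prev[k], search_px=2.0)
        if conf0 >= stereo_confidence and d0 > 0:
            ref_points[i] = triangulate_many(
                ref.rect, pos0[None, :], np.array([[pos0[0] - d0, pos0[1]]]), frame="left"
            )[0]
            disparity_prev[k] = d0

    fields: list[DeformationField] = []
    for t in range(T):
        if t == reference_frame:
            fields.append(
                DeformationField(
                    ids=np.arange(len(cloud0)), w=cloud0.left_px.copy(),
                    D=np.zeros(len(cloud0)), reference=ref_points.copy(),
                    current=ref_points.copy(),
                    stable=np.isin(np.arange(len(cloud0)), stable_sel),
                    confidence=np.ones(len(cloud0)),
                )
            )
            continue

        gL, gR = rect_frames_L[t], rect_frames_R[t]
        cur_recon = reconstruct_pair(
            rig, frames_L[t], frames_R[t], match_config=config,
            detector_params=detector_params,
        )

        pos_list, S_list, ok_idx = [], [], []
        for k, traj in enumerate(trajectories):
            if traj.status[t] != "tracked":
                continue
            pos = traj.positions[t]
            d, conf = _stereo_search(gL, gR, pos, disparity_prev[k])
            if conf < stereo_confidence or d <= 0:
                continue
            S_t = triangulate_many(
                ref.rect, pos[None, :], np.array([[pos[0] - d, pos[1]]]), frame="left"
            )[0]
            if np.linalg.norm(S_t - ref_points[stable_sel[k]]) > max_deformation_mm:
                continue
            traj.S[t] = S_t
            disparity_prev[k] = d
            pos_list.append(pos)
            S_list.append(S_t)
            ok_idx.append(k)

        ok_idx = np.asarray(ok_idx, dtype=int)
        if ok_idx.size:
            S_now = np.vstack(S_list)
            pos_now = np.vstack(pos_list)
            D_now = np.linalg.norm(S_now - ref_points[stable_sel[ok_idx]], axis=1)
            bad = _demote_inconsistent(pos_now, D_now)
            ok_idx, S_now, pos_now = ok_idx[~bad], S_now[~bad], pos_now[~bad]
        stable_pts_ids = stable_sel[ok_idx] if ok_idx.size else np.empty((0,), int)
        if ok_idx.size:
            stable_field = deformation_at_stable(
                S_now, ref_points[stable_pts_ids],
                ids_t=stable_pts_ids, ids_O=stable_pts_ids, w=pos_now,
            )
        else:
            S_now = np.empty((0, 3))
            stable_field = DeformationField.empty()

        # everything without a fresh 3D track this frame is unstable now
        unstable_ids = np.setdiff1d(np.arange(len(cloud0)), stable_pts_ids)
        warp = None
        if ok_idx.size >= 4:
            try:
                ctrl_src, ctrl_dst = _select_controls(
                    ref_points[stable_pts_ids], S_now
                )
                warp = fit_tps(ctrl_src, ctrl_dst, lam=tps_lambda)
            except DegenerateConfigurationError:
                warp = None
        if warp is not None and unstable_ids.size:
            unstable_field = map_unstable(
                warp, ref_points[unstable_ids], ref_points[unstable_ids],
                cur_recon.cloud, ref.rect, ids=unstable_ids, radius_px=radius_px,
                max_deformation_mm=max_deformation_mm,
            )
        else:
            unstable_field = DeformationField.empty()
        fields.append(merge_fields(stable_field, unstable_field))

    return DeformationSequence(
        fields=fields, reference=ref, trajectories=trajectories,
        stable_ids=stable_sel, reference_frame=reference_frame,
    )


def force_from_deformation(
    field: DeformationField,
    model: ForceDisplacementModel,
    tool_region: DiskRegion | None = None,
    fit_baseline: bool = True,
    min_confidence: float = 0.9,
) -> tuple[ForceEstimate, GaussianIndentation]:
    """Estimate the tool-tip force from one frame's deformation field.

    Surface positions are the tangent-plane (x, y) coordinates of the
    reference structure; samples under ``tool_region`` (the occluded tool
    tip, mm) and low-confidence TPS-fallback samples are excluded before the
    Gaussian peak inference, which then extrapolates the occluded peak from
    the visible displacement ring.
    """
    sel = field.confidence >= min_confidence
    positions = field.reference[sel, :2]
    indent = fit_indentation(
        positions, field.D[sel], tool_region=tool_region, fit_baseline=fit_baseline
    )
    return estimate_force(model, indent), indent
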