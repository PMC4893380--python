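"""Constrained global matching, densification, normals, propagation."""

import numpy as np
import pytest

from stereodeform.exceptions import InvalidFeatureError
from stereodeform.features import DetectorParams, FeatureRegion, appearance_similarity, detect_regions, ellipse_overlap
from stereodeform.geometry import rectify_pair
from stereodeform.matching import (
    LightModel,
    MatchConfig,
    PointCloud,
    StereoMatch,
    SurfaceNormalMap,
    densify_local,
    estimate_normals,
    match_global,
    normal_from_pq,
    propagate_matches,
    reconstruct,
    similarity_score,
)
from stereodeform.synthdata import SceneParams, gt_correspondences, make_scene, render_stereo


def brute_force_match(feats_L, feats_R, config):
    """Independent exhaustive implementation of the constrained argmax match.

    Scores every (i, j) pair, applies the epipolar band and the two
    constraints, takes the per-left argmax with the documented tie-breaks,
    then enforces right-uniqueness keeping the strongest claim.
    """
    fl = sorted(feats_L, key=lambda f: (f.x[1], f.x[0], -f.c))
    fr = sorted(feats_R, key=lambda f: (f.x[1], f.x[0], -f.c))
    claims = {}
    for f_i in fl:
        best_key, best_j = None, None
        for j, f_j in enumerate(fr):
            if abs(f_i.x[1] - f_j.x[1]) > config.epipolar_tolerance:
                continue
            A = appearance_similarity(f_i.patch, f_j.patch)
            if A <= config.thr_s:
                continue
            iou = ellipse_overlap((f_i.x, f_i.shape), (f_i.x, f_j.shape))
            if iou <= config.thr_r:
                continue
            M = iou + min(f_i.c, f_j.c) / max(f_i.c, f_j.c)
            key = (M, A, -abs(f_i.x[0] - f_j.x[0]))
            if best_key is None or key > best_key:
                best_key, best_j = key, j
        if best_j is not None:
            full = best_key + (-f_i.x[1], -f_i.x[0])
            if best_j not in claims or full > claims[best_j][0]:
                claims[best_j] = (full, f_i)
    return {
        (round(f.x[0], 6), round(f.x[1], 6), round(fr[j].x[0], 6), round(fr[j].x[1], 6))
        for j, (_, f) in claims.items()
    }


def _circle_feature(x, c=1.0, r=4.0, patch=None, rng=None):
    if patch is None:
        patch = (rng or np.random.default_rng(0)).random((21, 21))
    return FeatureRegion(x=np.asarray(x, float), c=c, shape=r**2 * np.eye(2), patch=patch)


class TestSimilarityScore:
    def test_identical_regions_equal_saliency(self, rng):
        f = _circle_feature([10, 10], c=2.5, rng=rng)
        g = _circle_feature([10, 10], c=2.5, rng=rng)
        assert similarity_score(f, g) == pytest.approx(2.0, abs=1e-9)

    def test_disjoint_regions_saliency_ratio_only(self, rng):
        f = _circle_feature([0, 0], c=1.0, rng=rng)
        g = _circle_feature([100, 0], c=2.0, rng=rng)
        assert similarity_score(f, g) == pytest.approx(0.5, abs=1e-9)

    def test_overlapping_circles_match_oracle_composition(self, rng):
        from test_features import _rasterized_iou

        S = 100.0 * np.eye(2)
        f = FeatureRegion(x=[0.0, 0.0], c=3.0, shape=S, patch=rng.random((21, 21)))
        g = FeatureRegion(x=[10.0, 0.0], c=4.0, shape=S, patch=rng.random((21, 21)))
        oracle = _rasterized_iou([0, 0], S, [10, 0], S) + 0.75
        assert similarity_score(f, g) == pytest.approx(oracle, abs=1e-3)

    def test_nonpositive_saliency_rejected(self, rng):
        f = _circle_feature([0, 0], rng=rng)
        g = _circle_feature([0, 0], rng=rng)
        g.c = 0.0  # bypass constructor validation
        with pytest.raises(InvalidFeatureError):
            similarity_score(f, g)


class TestMatchGlobal:
    def test_single_admissible_candidate_is_matched(self, rng):
        patch = rng.random((21, 21))
        left = [_circle_feature([50, 20], patch=patch)]
        right = [_circle_feature([40, 20.5], patch=patch + 0.001 * rng.random((21, 21)))]
        out = match_global(left, right, MatchConfig())
        assert len(out) == 1
        assert out[0].stage == "global"
        assert out[0].A > 0.9 and out[0].M > 1.6

    def test_low_appearance_candidates_excluded(self, rng):
        left = [_circle_feature([50, 20], patch=rng.random((21, 21)))]
        right = [_circle_feature([40, 20], patch=rng.random((21, 21)))]
        assert match_global(left, right, MatchConfig()) == []

    def test_epipolar_band_excludes_distant_rows(self, rng):
        patch = rng.random((21, 21))
        left = [_circle_feature([50, 20], patch=patch)]
        right = [_circle_feature([40, 25], patch=patch)]
        assert match_global(left, right, MatchConfig()) == []

    def test_equals_exhaustive_oracle_on_rendered_pair(self, small_recon):
        feats_L = small_recon.features_L[:150]
        feats_R = small_recon.features_R[:150]
        config = MatchConfig()
        ours = {
            (round(m.left.x[0], 6), round(m.left.x[1], 6),
             round(m.right.x[0], 6), round(m.right.x[1], 6))
            for m in match_global(feats_L, feats_R, config)
        }
        assert ours == brute_force_match(feats_L, feats_R, config)

    def test_output_invariant_to_input_ordering(self, small_recon, rng):
        feats_L = list(small_recon.features_L[:120])
        feats_R = list(small_recon.features_R[:120])
        config = MatchConfig()
        base = match_global(feats_L, feats_R, config)
        rng.shuffle(feats_L)
        rng.shuffle(feats_R)
        shuffled = match_global(feats_L, feats_R, config)
        key = lambda m: (round(m.left.x[0], 9), round(m.left.x[1], 9))
        assert [key(m) for m in base] == [key(m) for m in shuffled]

    def test_raising_appearance_threshold_never_adds_matches(self, small_recon):
        feats_L = small_recon.features_L[:200]
        feats_R = small_recon.features_R[:200]
        counts = [
            len(match_global(feats_L, feats_R, MatchConfig(thr_s=t)))
            for t in (0.85, 0.90, 0.95, 0.99)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_right_feature_matched_at_most_once(self, small_recon):
        out = match_global(small_recon.features_L[:300], small_recon.features_R[:300])
        rights = [tuple(np.round(m.right.x, 9)) for m in out]
        assert len(rights) == len(set(rights))


class TestDensifyLocal:
    def test_textureless_seeds_add_nothing(self, rng):
        img = np.full((80, 80), 0.5)
        patch = rng.random((21, 21))
        seed = StereoMatch(
            left=_circle_feature([40, 40], patch=patch),
            right=_circle_feature([30, 40], patch=patch), M=2.0, A=1.0,
        )
        out = densify_local([seed], img, img, MatchConfig())
        assert out == [seed]

    def test_added_matches_obey_constraints_and_count_increases(self, small_recon):
        config = MatchConfig()
        seeds = match_global(small_recon.features_L, small_recon.features_R, config)[:30]
        out = densify_local(seeds, small_recon.img_L, small_recon.img_R, config)
        assert len(out) > len(seeds)  # superset with additions on textured scene
        assert out[: len(seeds)] == seeds
        for m in out[len(seeds):]:
            assert m.stage == "local"
            assert abs(m.left.x[1] - m.right.x[1]) <= config.epipolar_tolerance
            assert m.A > config.thr_s


class TestNormals:
    def test_formula_flat_and_unit_slope(self):
        assert np.allclose(normal_from_pq(0.0, 0.0), [0, 0, -1])
        assert np.allclose(normal_from_pq(1.0, 0.0), [1 / np.sqrt(2), 0, -1 / np.sqrt(2)])

    def test_unit_norm_and_negative_z_everywhere(self, small_render0):
        nm = estimate_normals(small_render0.img_L)
        norms = np.linalg.norm(nm.normals, axis=-1)
        assert np.allclose(norms, 1.0, atol=1e-9)
        assert np.all(nm.normals[..., 2] < 0)

    def test_fronto_parallel_plane_reads_flat(self):
        scene = make_scene(SceneParams(surface="plane", image_size=(320, 240)), seed=13)
        r = render_stereo(scene, 0)
        lm = LightModel(focal=scene.rig.K_L[0, 0],
                        cx=scene.rig.K_L[0, 2], cy=scene.rig.K_L[1, 2])
        nm = estimate_normals(r.img_L, lm)
        interior = nm.normals[30:-30, 30:-30]
        angles = np.degrees(np.arccos(np.clip(-interior[..., 2], -1, 1)))
        assert np.mean(angles < 1.0) >= 0.90


class TestPropagation:
    def _seed(self, rng, shape_l=None, shape_r=None):
        shape_l = 36.0 * np.eye(2) if shape_l is None else shape_l
        shape_r = shape_l if shape_r is None else shape_r
        patch = rng.random((21, 21))
        return StereoMatch(
            left=FeatureRegion(x=[50.0, 30.0], c=1.0, shape=shape_l, patch=patch),
            right=FeatureRegion(x=[38.0, 30.0], c=1.0, shape=shape_r, patch=patch),
            M=2.0, A=1.0,
        )

    def test_identity_affine_predicts_pure_disparity_shift(self, rng):
        seed = self._seed(rng)
        cand = _circle_feature([52.0, 32.0], r=2.0, rng=rng)
        out = propagate_matches([seed], [cand], normals=None, config=MatchConfig())
        assert len(out) == 1
        # f_R = f_L + (seed_R - seed_L): disparity shift of 12 columns
        assert out[0].right.x == pytest.approx([40.0, 32.0])
        assert out[0].stage == "propagated"

    def test_normal_gate_rejects_two_degree_disagreement(self, rng):
        h, w = 60, 100
        p = np.zeros((h, w))
        p[:, 52:] = np.tan(np.radians(2.1))  # tilt only at the candidate
        normals = SurfaceNormalMap(p=p, q=np.zeros((h, w)))
        seed = self._seed(rng)
        cand = _circle_feature([55.0, 30.0], r=2.0, rng=rng)
        out = propagate_matches([seed], [cand], normals, MatchConfig())
        assert out == []

    def test_agreeing_normals_pass_gate(self, rng):
        normals = SurfaceNormalMap(p=np.zeros((60, 100)), q=np.zeros((60, 100)))
        seed = self._seed(rng)
        cand = _circle_feature([55.0, 30.0], r=2.0, rng=rng)
        assert len(propagate_matches([seed], [cand], normals, MatchConfig())) == 1

    def test_known_affine_warp_predicted_within_half_pixel(self, rng):
        # right view related to left by a known symmetric affine map T about
        # the seed; circular seed regions make the normalizing transforms
        # recover T exactly
        th = 0.4
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        T_true = R @ np.diag([1.3, 0.8]) @ R.T
        S_L = 25.0 * np.eye(2)
        S_R = T_true @ S_L @ T_true.T
        seed = self._seed(rng, shape_l=S_L, shape_r=S_R)
        for offset in ([3.0, 1.0], [-2.0, 2.5], [1.5, -3.0]):
            cand = _circle_feature(seed.left.x + offset, r=2.0, rng=rng)
            out = propagate_matches([seed], [cand], normals=None, config=MatchConfig(
                epipolar_tolerance=50.0))
            assert len(out) == 1
            expected = T_true @ np.asarray(offset) + seed.right.x
            assert np.max(np.abs(out[0].right.x - expected)) < 0.5


class TestReconstruct:
    def test_empty_matches_empty_cloud(self, small_recon):
        assert len(reconstruct([], small_recon.rect)) == 0

    def test_plane_fixture_points_on_plane(self, rng):
        scene = make_scene(SceneParams(surface="plane"), seed=17)
        P, xL, xR = gt_correspondences(scene, n=60, seed=4)
        rect, _, _ = rectify_pair(
            scene.rig,
            np.zeros((scene.rig.image_size[1], scene.rig.image_size[0])),
            np.zeros((scene.rig.image_size[1], scene.rig.image_size[0])),
        )
        matches = [
            StereoMatch(left=_circle_feature(xL[i], rng=rng),
                        right=_circle_feature(xR[i], rng=rng), M=2.0, A=1.0)
            for i in range(60)
        ]
        cloud = reconstruct(matches, rect, refine=False)
        assert np.max(np.abs(cloud.points[:, 2] - 100.0)) < 1e-3

    def test_point_count_conserves_matches_minus_rejections(self, rng):
        from test_geometry import _ideal_rect

        rect = _ideal_rect(cx=100, cy=100)
        patch = rng.random((21, 21))
        mk = lambda xl, xr: StereoMatch(
            left=_circle_feature(xl, patch=patch),
            right=_circle_feature(xr, patch=patch), M=2.0, A=1.0)
        matches = [
            mk([150.0, 100.0], [100.0, 100.0]),  # valid
            mk([150.0, 110.0], [150.0, 110.0]),  # zero disparity -> rejected
            mk([150.0, 120.0], [160.0, 120.0]),  # negative disparity -> rejected
            mk([90.0, 50.0], [60.0, 50.0]),      # valid
        ]
        cloud = reconstruct(matches, rect, refine=False)
        assert len(cloud) == 2

    def test_pipeline_precision_on_synthetic_fixture(self, default_scene, default_render0, default_recon):
        from scipy.ndimage import map_coordinates

        cloud = default_recon.cloud
        zgt = map_coordinates(
            default_render0.gt_depth_L, [cloud.left_px[:, 1], cloud.left_px[:, 0]], order=1
        )
        frac = np.mean(np.abs(cloud.points[:, 2] - zgt) < 1.0)
        assert frac >= 0.98
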