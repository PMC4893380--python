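"""Temporal tracking, deformation fields, 3D TPS, unstable-point mapping."""

import warnings

import numpy as np
import pytest
from scipy.ndimage import shift as nd_shift

from stereodeform.deformation import (
    DeformationField,
    TrackerConfig,
    deformation_at_stable,
    fit_tps,
    map_unstable,
    merge_fields,
    render_heatmap,
    save_heatmap,
    track_features,
)
from stereodeform.exceptions import DegenerateConfigurationError, StereoDeformError
from stereodeform.features import FeatureRegion
from stereodeform.matching import PointCloud


def _texture(rng, size=(120, 160)):
    from scipy.ndimage import gaussian_filter

    img = gaussian_filter(rng.random(size), 2.0)
    return (img - img.min()) / np.ptp(img)


def _features_on(img, n, rng, margin=20):
    h, w = img.shape
    xs = rng.uniform(margin, w - margin, n)
    ys = rng.uniform(margin, h - margin, n)
    return [
        FeatureRegion(x=[x, y], c=1.0, shape=25.0 * np.eye(2))
        for x, y in zip(xs, ys)
    ]


class TestTracker:
    def test_empty_sequence_rejected(self, rng):
        with pytest.raises(StereoDeformError):
            track_features([], [])

    def test_static_frames_stay_put(self, rng):
        img = _texture(rng)
        feats = _features_on(img, 15, rng)
        trajs = track_features([img] * 4, feats)
        for tr in trajs:
            drift = np.linalg.norm(tr.positions - tr.positions[0], axis=1)
            assert np.max(drift) <= 0.1
            assert all(s == "tracked" for s in tr.status)

    def test_known_translation_tracked_accurately(self, rng):
        img = _texture(rng)
        frames = [nd_shift(img, (0.0, 2.0 * t), order=3, mode="nearest") for t in range(4)]
        feats = _features_on(img, 20, rng, margin=25)
        trajs = track_features(frames, feats)
        errs = []
        for tr in trajs:
            for t in range(4):
                if tr.status[t] == "tracked":
                    expected = tr.positions[0] + [2.0 * t, 0.0]
                    errs.append(np.linalg.norm(tr.positions[t] - expected))
        assert np.mean(errs) < 0.5

    def test_occluded_feature_lost_within_two_frames(self, rng):
        img = _texture(rng)
        occluded = img.copy()
        occluded[40:80, 60:100] = 0.02  # dark tool square
        feats = [FeatureRegion(x=[80.0, 60.0], c=1.0, shape=25.0 * np.eye(2))]
        trajs = track_features([img, img, occluded, occluded], feats)
        assert trajs[0].status[0] == "tracked"
        assert "lost" in trajs[0].status[2:3] or "lost" in trajs[0].status[3:]
        assert trajs[0].status[3] == "lost"

    def test_teleport_guard_marks_lost(self, rng):
        img = _texture(rng)
        other = _texture(np.random.default_rng(999))  # unrelated content
        feats = _features_on(img, 10, rng)
        trajs = track_features([img, other], feats, TrackerConfig(max_step_px=5.0))
        for tr in trajs:
            # no tracked frame may move beyond the per-frame bound, and
            # nothing on unrelated content should track confidently
            if tr.status[1] == "tracked":
                assert np.linalg.norm(tr.positions[1] - tr.positions[0]) <= 5.0 + 1e-6
        assert sum(tr.status[1] == "lost" for tr in trajs) >= 8


class TestDeformationAtStable:
    def test_identical_clouds_zero(self, rng):
        S = rng.normal(size=(30, 3))
        field = deformation_at_stable(S, S.copy())
        assert np.allclose(field.D, 0.0)

    def test_three_four_five(self):
        S_O = np.array([[0.0, 0.0, 100.0]])
        S_t = np.array([[3.0, 4.0, 100.0]])
        field = deformation_at_stable(S_t, S_O)
        assert field.D[0] == pytest.approx(5.0, abs=1e-12)

    def test_matches_norm_oracle(self, rng):
        a = rng.normal(size=(50, 3)) * 20
        b = rng.normal(size=(50, 3)) * 20
        field = deformation_at_stable(a, b)
        oracle = np.sqrt(np.sum((a - b) ** 2, axis=1))
        assert np.max(np.abs(field.D - oracle)) < 1e-12

    def test_invariant_under_global_rigid_transform(self, rng):
        a = rng.normal(size=(40, 3)) * 15
        b = a + rng.normal(size=(40, 3))
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        t = np.array([5.0, -3.0, 11.0])
        d0 = deformation_at_stable(a, b).D
        d1 = deformation_at_stable(a @ R.T + t, b @ R.T + t).D
        assert np.allclose(d0, d1, atol=1e-9)

    def test_unmatched_ids_skipped_with_warning(self, rng):
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(6, 3))
        with pytest.warns(UserWarning, match="skipped"):
            field = deformation_at_stable(
                a, b, ids_t=np.arange(5), ids_O=np.arange(1, 7)
            )
        assert len(field) == 4


def _tps_oracle(src, dst, query):
    """Independent dense TPS solve: assemble and invert the full bordered
    system with lstsq, evaluate with an explicit double loop."""
    n = src.shape[0]
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = np.linalg.norm(src[i] - src[j])
    P = np.hstack([np.ones((n, 1)), src])
    A = np.zeros((n + 4, n + 4))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    b = np.vstack([dst, np.zeros((4, 3))])
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    W, aff = sol[:n], sol[n:]
    out = np.zeros((query.shape[0], 3))
    for q in range(query.shape[0]):
        acc = aff[0] + aff[1:].T @ query[q]
        for i in range(n):
            acc = acc + W[i] * np.linalg.norm(query[q] - src[i])
        out[q] = acc
    return out


class TestTPS:
    def test_zero_lambda_interpolates_exactly(self, rng):
        src = rng.normal(size=(12, 3)) * 10
        dst = src + rng.normal(size=(12, 3)) * 2
        warp = fit_tps(src, dst, lam=0.0)
        assert np.max(np.abs(warp.transform(src) - dst)) < 1e-8

    def test_side_conditions_hold(self, rng):
        src = rng.normal(size=(15, 3)) * 10
        dst = src + rng.normal(size=(15, 3))
        warp = fit_tps(src, dst)
        P = np.hstack([np.ones((15, 1)), src])
        assert np.max(np.abs(P.T @ warp.weights)) < 1e-8

    def test_affine_targets_reproduced_on_held_out_points(self, rng):
        src = rng.normal(size=(20, 3)) * 10
        A = np.array([[1.1, 0.2, 0.0], [-0.1, 0.9, 0.05], [0.0, 0.1, 1.05]])
        t = np.array([2.0, -1.0, 4.0])
        dst = src @ A.T + t
        warp = fit_tps(src, dst, lam=0.0)
        assert np.max(np.abs(warp.weights)) < 1e-6  # pure affine: no kernel part
        held_out = rng.normal(size=(50, 3)) * 10
        assert np.max(np.abs(warp.transform(held_out) - (held_out @ A.T + t))) < 1e-6

    def test_agrees_with_independent_dense_solve(self, rng):
        src = rng.normal(size=(20, 3)) * 10
        dst = src + rng.normal(size=(20, 3)) * 3
        query = rng.normal(size=(50, 3)) * 10
        warp = fit_tps(src, dst, lam=0.0)
        assert np.max(np.abs(warp.transform(query) - _tps_oracle(src, dst, query))) < 1e-8

    def test_too_few_controls_rejected(self, rng):
        src = rng.normal(size=(3, 3))
        with pytest.raises(DegenerateConfigurationError):
            fit_tps(src, src)

    def test_coplanar_controls_rejected(self, rng):
        src = rng.normal(size=(10, 3))
        src[:, 2] = 5.0  # all in one plane
        with pytest.raises(DegenerateConfigurationError):
            fit_tps(src, src)


def _identity_rect():
    from test_geometry import _ideal_rect

    return _ideal_rect(f=1000.0, b=5.0, cx=320.0, cy=240.0)


def _cloud_from(points, rect):
    from stereodeform.geometry import project_rectified

    px = project_rectified(rect, points, camera="L")
    return PointCloud(
        points=np.asarray(points, float), left_px=px, right_px=px.copy(),
        stages=np.array(["global"] * len(points), dtype=object),
        ids=np.arange(len(points)),
    )


class TestMapUnstable:
    def _warp(self, rng, delta=None):
        src = rng.normal(size=(16, 3)) * np.array([20, 15, 3]) + [0, 0, 100]
        dst = src if delta is None else src + delta
        return fit_tps(src, dst, lam=0.0), src

    def test_zero_motion_identity(self, rng):
        warp, src = self._warp(rng)
        rect = _identity_rect()
        pts = rng.normal(size=(10, 3)) * np.array([15, 10, 2]) + [0, 0, 100]
        cloud = _cloud_from(pts, rect)
        field = map_unstable(warp, pts, pts, cloud, rect)
        assert np.allclose(field.D, 0.0, atol=1e-6)
        assert np.all(field.confidence == 1.0)  # snapped to reconstruction

    def test_no_nearby_reconstruction_still_reported_low_confidence(self, rng):
        warp, _ = self._warp(rng)
        rect = _identity_rect()
        pts = np.array([[0.0, 0.0, 100.0]])
        field = map_unstable(warp, pts, pts, PointCloud.empty(), rect)
        assert len(field) == 1
        assert field.confidence[0] == 0.5
        assert not field.stable[0]

    def test_behind_camera_points_dropped_with_warning(self, rng):
        src = rng.normal(size=(10, 3)) + [0, 0, 100]
        dst = src - [0, 0, 250]  # warp throws points behind the camera
        warp = fit_tps(src, dst, lam=0.0)
        rect = _identity_rect()
        pts = src[:3]
        with pytest.warns(UserWarning, match="behind"):
            field = map_unstable(warp, pts, pts, PointCloud.empty(), rect)
        assert len(field) == 0


class TestHeatmap:
    def _field(self, rng, D):
        n = len(D)
        w = np.column_stack([rng.uniform(60, 260, n), rng.uniform(40, 200, n)])
        pts = np.column_stack([w * 0.1, np.full(n, 100.0)])[:, [0, 1, 2]]
        return DeformationField(
            ids=np.arange(n), w=w, D=np.asarray(D, float),
            reference=pts, current=pts, stable=np.ones(n, bool),
            confidence=np.ones(n),
        )

    def test_zero_field_uniform_minimum_color(self, rng):
        field = self._field(rng, np.zeros(30))
        img = rng.random((240, 320))
        rgb, vmax = render_heatmap(field, img)
        assert vmax == 0.0
        assert rgb.shape == (240, 320, 3)

    def test_colormap_maximum_equals_max_deformation(self, rng):
        D = rng.random(40) * 7.5
        field = self._field(rng, D)
        _, vmax = render_heatmap(field, rng.random((240, 320)))
        assert vmax == pytest.approx(D.max())

    def test_peak_location_carries_top_color_bin(self, rng):
        # Gaussian bump of D values centered mid-image
        n = 200
        w = np.column_stack([rng.uniform(20, 300, n), rng.uniform(20, 220, n)])
        center = np.array([160.0, 120.0])
        D = 8.0 * np.exp(-np.sum((w - center) ** 2, axis=1) / (2 * 40.0**2))
        field = DeformationField(
            ids=np.arange(n), w=w, D=D,
            reference=np.zeros((n, 3)), current=np.zeros((n, 3)),
            stable=np.ones(n, bool), confidence=np.ones(n),
        )
        img = np.full((240, 320), 0.5)
        rgb, vmax = render_heatmap(field, img, cmap="inferno", alpha=1.0)
        from matplotlib import colormaps

        top = np.array(colormaps["inferno"](np.max(D) / vmax)[:3]) * 255
        got = rgb[120, 160].astype(float)
        assert np.linalg.norm(got - top) < 40  # within the top color bin

    def test_save_heatmap_writes_png_with_mm_legend(self, rng, tmp_path):
        field = self._field(rng, rng.random(25) * 3)
        out = tmp_path / "overlay.png"
        vmax = save_heatmap(field, rng.random((240, 320)), out)
        assert out.exists() and out.stat().st_size > 0
        assert vmax == pytest.approx(field.D.max())

    def test_empty_field_rejected(self, rng):
        with pytest.raises(ValueError):
            render_heatmap(DeformationField.empty(), rng.random((50, 50)))


class TestMergeFields:
    def test_concatenates_parts(self, rng):
        a = deformation_at_stable(rng.normal(size=(5, 3)), rng.normal(size=(5, 3)))
        b = deformation_at_stable(rng.normal(size=(3, 3)), rng.normal(size=(3, 3)))
        merged = merge_fields(a, b)
        assert len(merged) == 8
        assert np.allclose(merged.D[:5], a.D)
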