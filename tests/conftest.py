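"""Shared fixtures: synthetic scenes and pipeline runs reused across tests.

Heavy products (renders, full reconstructions, the tracked deformation
sequence) are session-scoped so the suite pays for each of them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from stereodeform.features import DetectorParams
from stereodeform.pipeline import reconstruct_pair, track_and_deform
from stereodeform.synthdata import SceneParams, make_scene, render_stereo


@pytest.fixture(scope="session")
def default_scene():
    """Default-geometry scene: 100 mm depth, 6 mm baseline, 640x480."""
    return make_scene(SceneParams(image_size=(640, 480)), seed=1)


@pytest.fixture(scope="session")
def default_render0(default_scene):
    return render_stereo(default_scene, 0)


@pytest.fixture(scope="session")
def default_recon(default_scene, default_render0):
    """Full quasi-dense reconstruction of the default fixture's first frame."""
    r = default_render0
    return reconstruct_pair(default_scene.rig, r.img_L, r.img_R)


@pytest.fixture(scope="session")
def small_scene():
    """Small textured scene for fast matching/feature tests."""
    return make_scene(SceneParams(image_size=(320, 240), n_frames=3,
                                  max_amplitude_mm=6.0), seed=7)


@pytest.fixture(scope="session")
def small_render0(small_scene):
    return render_stereo(small_scene, 0)


@pytest.fixture(scope="session")
def small_recon(small_scene, small_render0):
    r = small_render0
    return reconstruct_pair(
        small_scene.rig, r.img_L, r.img_R,
        detector_params=DetectorParams(max_features=800),
    )


@pytest.fixture(scope="session")
def deform_scene():
    """Indentation sequence fixture: 10 mm scheduled over 6 frames."""
    return make_scene(
        SceneParams(image_size=(480, 360), n_frames=6, max_amplitude_mm=10.0),
        seed=3,
    )


@pytest.fixture(scope="session")
def deform_frames(deform_scene):
    return [render_stereo(deform_scene, t) for t in range(deform_scene.n_frames)]


@pytest.fixture(scope="session")
def deform_run(deform_scene, deform_frames):
    """Tracked deformation sequence over the full indentation schedule."""
    return track_and_deform(
        deform_scene.rig,
        [f.img_L for f in deform_frames],
        [f.img_R for f in deform_frames],
        detector_params=DetectorParams(max_features=1500),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
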