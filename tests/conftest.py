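import dataclasses

import numpy as np
import pytest

from rootball import SceneSpec, generate_root_scene, render_views


@pytest.fixture(scope="session")
def default_scene():
    """One default synthetic scene shared by read-only tests."""
    spec = SceneSpec(seed=7)
    panorama, gt = generate_root_scene(spec)
    return spec, panorama, gt


@pytest.fixture(scope="session")
def noisefree_views(default_scene):
    spec, panorama, gt = default_scene
    frames = render_views(panorama, gt, noise_sd=0.0, spec=spec, seed=spec.seed)
    return spec, panorama, gt, frames


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def straight_scene_spec(seed=0, width=5.0, length=200.0):
    """A single straight root at 0.02 cm/px (camera 150 mm from a 30 mm plug)."""
    return dataclasses.replace(
        SceneSpec(seed=seed), n_roots=1, width_range=(width, width),
        root_length_range=(length, length), curve_sd=0.0,
        camera_distance_mm=150.0, cylinder_radius_mm=30.0, focal_px=600.0)
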