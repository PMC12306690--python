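"""Shared fixtures: synthetic scenes and derived measurement products."""

from __future__ import annotations

import numpy as np
import pytest

from retvasc.biomarkers import compute_feature_set
from retvasc.regions import disc_geometry
from retvasc.synthetic import SceneConfig, generate_scene
from retvasc.vesselgraph import mask_to_graph


@pytest.fixture(scope="session")
def default_scene():
    """The default 1024 px scene with planted ground truth."""
    return generate_scene(SceneConfig())


@pytest.fixture(scope="session")
def default_graphs(default_scene):
    scene = default_scene
    return (
        mask_to_graph(scene.artery_mask, "artery"),
        mask_to_graph(scene.vein_mask, "vein"),
    )


@pytest.fixture(scope="session")
def default_measured_features(default_scene, default_graphs):
    scene = default_scene
    artery, vein = default_graphs
    disc = disc_geometry(scene.disc_mask)
    return compute_feature_set(
        artery,
        vein,
        scene.artery_mask,
        scene.vein_mask,
        disc,
        (scene.fovea.x, scene.fovea.y),
        scene.bounds_truth,
    )


def disk_image(size, center, radius, value=0.8):
    """Plain bright-disk RGB image for bounds-detection tests."""
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w]
    inside = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2
    img = np.zeros((h, w, 3))
    img[inside] = value
    return img
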