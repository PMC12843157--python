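"""Shared fixtures: small synthetic scenes and cached pipeline runs."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import gcodeqc as g
from gcodeqc import pipeline, register


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def co_mesh():
    return g.make_calibration_object()


@pytest.fixture(scope="session")
def small_box_scene():
    """10 x 10 x 2 mm box + calibration object, identity placement."""
    return g.compose_scene(g.make_box((10.0, 10.0, 2.0)))


@pytest.fixture(scope="session")
def small_box_gcode(small_box_scene):
    return g.mini_slice(small_box_scene)


@pytest.fixture(scope="session")
def small_box_toolpath(small_box_gcode):
    return g.parse_gcode(small_box_gcode)


@pytest.fixture(scope="session")
def small_box_stages(small_box_toolpath):
    """(pc4, vmap, stats) of the small box scene at default settings."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.correct_cloud(small_box_toolpath, g.RunConfig())


@pytest.fixture(scope="session")
def small_box_split(small_box_stages):
    pc4, vmap, _ = small_box_stages
    return register.split_calibration(pc4, vmap)


@pytest.fixture(scope="session")
def small_box_result(small_box_scene):
    """Full pipeline result for the small box scene."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return g.run_scene(small_box_scene)


@pytest.fixture(scope="session")
def rotated_box_result():
    """Full pipeline on a rotated + translated placement (registration
    actually has work to do here)."""
    scene = g.compose_scene(
        g.make_box((10.0, 10.0, 2.0)),
        g.RigidTransform.from_rotvec_deg([0, 0, 1], 3.0, (40.0, 25.0, 0.0)),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return scene, g.run_scene(scene)


def assert_rigid(T: g.RigidTransform, atol=1e-9):
    R = T.rotation
    np.testing.assert_allclose(R.T @ R, np.eye(3), atol=atol)
    assert np.linalg.det(R) > 0
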