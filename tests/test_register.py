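"""Calibration-object splitting, pre-alignment, ICP and transform algebra."""

import numpy as np
import pytest
import trimesh

import gcodeqc as g
from gcodeqc import pipeline, register
from gcodeqc.cloud import StagedPointCloud
from gcodeqc.errors import CalibrationNotFoundError, SplitError
from gcodeqc.fixtures import FixtureScene
from gcodeqc.metrics import surface_metrics_points
from tests.conftest import assert_rigid


def _cloud(points):
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    return StagedPointCloud(
        pts, np.arange(-1, n - 1), np.append(np.arange(1, n), -1),
        np.zeros(n, np.int64), np.zeros(n, np.int64),
        np.tile([1.0, 0, 0], (n, 1)), stage="PC4",
    )


def _surface_cloud(mesh, n=4000, seed=0):
    pts, _ = trimesh.sample.sample_surface(mesh, n, seed=seed)
    return _cloud(pts)


class TestSplit:
    def test_fixture_scene_finds_calibration_box(self, small_box_split):
        pco, pcm = small_box_split
        assert pco.role == "CALIBRATION"
        assert pcm.role == "MODEL"
        ext = pco.points.max(axis=0) - pco.points.min(axis=0)
        np.testing.assert_allclose(ext, [10.0, 6.25, 8.75], atol=0.5)

    def test_split_is_a_partition(self, small_box_split, small_box_stages):
        pco, pcm = small_box_split
        pc4, _, _ = small_box_stages
        assert len(pco) + len(pcm) == len(pc4)

    def test_single_component_scene_rejected(self):
        tp = g.parse_gcode(
            "G90\nM82\nG1 X1 Y1 Z0.2 E0\nG1 X9 E0.5",
            g.ProcessMeta(0.2, 0.4),
        )
        pc1 = g.extract_centerline_points(tp, spacing=0.05)
        vmap = g.classify_labels(g.voxelize(pc1, 0.4, 0.2, 0.1))
        pc2 = g.shell_filter(pc1, vmap, w=0.4, h=0.2)
        with pytest.raises(SplitError, match="2"):
            register.split_calibration(pc2, vmap)

    def test_twin_cubes_have_no_calibration(self):
        # two cube-like components, neither matching the step dimensions
        box2 = g.make_box((20.0, 20.0, 2.0))
        scene = FixtureScene(
            model_mesh=g.make_box((20.0, 20.0, 2.0)).apply_translation((30, 0, 0)),
            co_mesh=box2,
        )
        tp = g.parse_gcode(g.mini_slice(scene))
        pc4, vmap, _ = pipeline.correct_cloud(tp, g.RunConfig())
        with pytest.raises(CalibrationNotFoundError):
            register.split_calibration(pc4, vmap)


class TestComPrealign:
    def test_centered_cloud_zero_translation(self, co_mesh):
        com = np.asarray(co_mesh.center_mass)
        offsets = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 2.0, 0],
                            [0, -2.0, 0], [0, 0, 3.0], [0, 0, -3.0]])
        pc = _cloud(com + offsets)   # point mean == volumetric centroid
        T = register.com_prealign(pc, co_mesh)
        np.testing.assert_allclose(T.translation, 0.0, atol=1e-12)
        np.testing.assert_allclose(T.rotation, np.eye(3))

    def test_shifted_cloud_recovers_shift(self, co_mesh):
        com = np.asarray(co_mesh.center_mass)
        offsets = np.array([[1.0, 1.0, 0], [-1.0, -1.0, 0]])
        pc = _cloud(com + offsets + np.array([100.0, 100.0, 0.0]))
        T = register.com_prealign(pc, co_mesh)
        np.testing.assert_allclose(T.translation, [-100.0, -100.0, 0.0], atol=0.05)

    def test_pure_z_shift(self, co_mesh):
        com = np.asarray(co_mesh.center_mass)
        pc = _cloud(com + np.array([[0.5, 0, 7.3], [-0.5, 0, 7.3]]))
        T = register.com_prealign(pc, co_mesh)
        np.testing.assert_allclose(T.translation, [0.0, 0.0, -7.3], atol=0.05)


class TestICP:
    def test_self_registration_is_identity(self, co_mesh):
        pco = _surface_cloud(co_mesh)
        T = register.icp_refine(pco, co_mesh, g.RigidTransform.identity())
        assert np.abs(T.translation).max() <= 1e-6
        assert T.rotation_angle_deg() <= 1e-6
        assert T.residual_rms <= 1e-9

    def test_known_transform_recovery(self, co_mesh):
        place = g.RigidTransform.from_rotvec_deg([0, 0, 1], 3.0, (50.0, 25.0, 0.0))
        pco = _cloud(place.apply(_surface_cloud(co_mesh).points))
        init = register.com_prealign(pco, co_mesh)
        T = register.icp_refine(pco, co_mesh, init)
        truth = place.inverse()
        assert np.abs(T.translation - truth.translation).max() <= 0.01
        assert T.compose(truth.inverse()).rotation_angle_deg() <= 0.05

    def test_flipped_init_is_flagged(self, co_mesh):
        # 180-degree flip about the object's own centroid: the center of
        # mass still matches but the orientation is wrong; the step
        # asymmetry makes this distinguishable from the true optimum
        pco = _surface_cloud(co_mesh)
        com = np.asarray(co_mesh.center_mass)
        flip = g.RigidTransform.from_rotvec_deg([1, 0, 0], 180.0)
        bad_init = (
            g.RigidTransform.from_translation(com)
            .compose(flip)
            .compose(g.RigidTransform.from_translation(-com))
        )
        try:
            T = register.icp_refine(pco, co_mesh, bad_init)
            residual_or_rotation_wrong = (
                T.residual_rms > 0.1 or T.rotation_angle_deg() > 5.0
            )
            assert residual_or_rotation_wrong
        except g.GCodeQCError:
            pass                              # divergence is also acceptable

    def test_deterministic(self, co_mesh):
        pco = _surface_cloud(co_mesh, seed=3)
        init = register.com_prealign(pco, co_mesh)
        a = register.icp_refine(pco, co_mesh, init)
        b = register.icp_refine(pco, co_mesh, init)
        assert np.array_equal(a.rotation, b.rotation)
        assert np.array_equal(a.translation, b.translation)


class TestApplyTransform:
    def test_identity_is_bit_identical(self, small_box_split):
        _, pcm = small_box_split
        out = register.apply_transform(pcm, g.RigidTransform.identity())
        assert np.array_equal(out.points, pcm.points)
        assert out.role == "TPCM"
        assert out.stage == pcm.stage

    def test_inverse_composition(self, small_box_split):
        _, pcm = small_box_split
        T = g.RigidTransform.from_rotvec_deg([1, 1, 0], 17.0, (3.0, -2.0, 9.0))
        back = register.apply_transform(
            register.apply_transform(pcm, T), T.inverse()
        )
        assert np.abs(back.points - pcm.points).max() <= 1e-9

    def test_rigidity_preserves_pairwise_distances(self, small_box_split):
        _, pcm = small_box_split
        T = g.RigidTransform.from_rotvec_deg([0, 1, 0], 42.0, (100.0, 5.0, 1.0))
        out = register.apply_transform(pcm, T)
        idx = np.linspace(0, len(pcm) - 1, 40).astype(int)
        d0 = np.linalg.norm(
            pcm.points[idx][:, None] - pcm.points[idx][None], axis=-1
        )
        d1 = np.linalg.norm(
            out.points[idx][:, None] - out.points[idx][None], axis=-1
        )
        assert np.abs(d0 - d1).max() <= 1e-9


class TestRigidTransform:
    def test_reflection_rejected(self):
        with pytest.raises(ValueError):
            g.RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_matrix_round_trip(self):
        T = g.RigidTransform.from_rotvec_deg([0, 0, 1], 33.0, (1.0, 2.0, 3.0))
        back = g.RigidTransform.from_matrix(T.to_matrix())
        assert_rigid(back)
        np.testing.assert_allclose(back.rotation, T.rotation, atol=1e-15)
        np.testing.assert_allclose(back.translation, T.translation, atol=1e-15)


class TestEndToEnd:
    def test_known_translation_msd_impact(self, co_mesh):
        # pure-translation placement: the surface metrics under the
        # recovered transform differ negligibly from the ground truth
        scene = g.compose_scene(
            g.make_box((10.0, 10.0, 2.0)),
            g.RigidTransform.from_translation((100.0, 100.0, 0.0)),
        )
        tp = g.parse_gcode(g.mini_slice(scene))
        pc4, vmap, _ = pipeline.correct_cloud(tp, g.RunConfig())
        pco, pcm = register.split_calibration(pc4, vmap)
        T = register.register_calibration(pco, scene.co_mesh)
        truth = scene.placement.inverse()
        msd_rec = surface_metrics_points(T.apply(pcm.points), scene.model_mesh).msd
        msd_true = surface_metrics_points(
            truth.apply(pcm.points), scene.model_mesh
        ).msd
        assert abs(msd_rec - msd_true) < 0.001
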