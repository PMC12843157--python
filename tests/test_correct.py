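"""Shell filtering, XY offset with infill decision logic, Z correction."""

import numpy as np
import pytest

import gcodeqc as g
from gcodeqc import correct, pipeline, register
from gcodeqc.cloud import (
    VERDICT_BOTH,
    VERDICT_KEEP_DOUBLE,
    VERDICT_KEEP_PRIME,
    StagedPointCloud,
)
from gcodeqc.errors import StageError
from gcodeqc.gcode import ProcessMeta, extract_centerline_points, parse_gcode
from gcodeqc.verification import deposition_plane_fraction
from gcodeqc.voxel import EMPTY, INTERIOR, SHELL, VoxelLabelMap

W, H = 0.4, 0.2


def _line_cloud(points, tangents=None, stage="PC2"):
    """Minimal hand-built cloud along one path."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if tangents is None:
        tangents = np.tile([1.0, 0.0, 0.0], (n, 1))
    prev = np.arange(-1, n - 1)
    nxt = np.append(np.arange(1, n), -1)
    return StagedPointCloud(
        pts, prev, nxt, np.zeros(n, np.int64), np.zeros(n, np.int64),
        np.asarray(tangents, float), stage=stage,
    )


def _flat_map(labeler, dims=(40, 40, 8), voxel=0.1):
    """Label map built from a function (ix, iy, iz) -> label."""
    labels = np.zeros(dims, dtype=np.uint8)
    for idx in np.ndindex(dims):
        labels[idx] = labeler(*idx)
    return VoxelLabelMap(np.zeros(3), voxel, labels, classified=True)


class TestShellFilter:
    def test_thin_single_wall_keeps_everything(self):
        # one straight extrusion line with nothing around it: every voxel
        # of the dilated bead touches the exterior, all points retained
        tp = parse_gcode(
            "G90\nM82\nG1 X1 Y1 Z0.2 E0\nG1 X9 E0.5", ProcessMeta(H, W)
        )
        pc1 = extract_centerline_points(tp, spacing=0.05)
        vmap = g.classify_labels(g.voxelize(pc1, W, H, 0.1))
        pc2 = g.shell_filter(pc1, vmap, w=W, h=H)
        assert len(pc2) == len(pc1)
        assert pc2.stage == "PC2"

    def test_fixture_cube_removes_interior_points(
        self, small_box_stages, small_box_toolpath, small_box_scene
    ):
        # retained mid-layer points must hug the boundary: no PC2 point of
        # a middle layer lies deeper than one line width + quantization
        pc4, vmap, stats = small_box_stages
        pc1 = extract_centerline_points(small_box_toolpath, spacing=0.05)
        pc2 = g.shell_filter(pc1, vmap, w=W, h=H)
        assert len(pc2) < len(pc1)          # infill and inner perimeter gone
        model = small_box_scene.model_mesh
        lo, hi = model.bounds
        mid = (
            (pc2.points[:, 2] > lo[2] + 2 * H)
            & (pc2.points[:, 2] < hi[2] - 2 * H)
            & (pc2.points[:, 0] > lo[0] - 2)  # model component only
            & (pc2.points[:, 0] < hi[0] + 2)
        )
        depth = np.minimum.reduce([
            pc2.points[mid, 0] - lo[0], hi[0] - pc2.points[mid, 0],
            pc2.points[mid, 1] - lo[1], hi[1] - pc2.points[mid, 1],
        ])
        assert depth.max() <= W + 2 * vmap.voxel_size

    def test_empty_shell_error(self):
        vmap = _flat_map(lambda i, j, k: EMPTY, dims=(10, 10, 10))
        pc1 = _line_cloud([[0.5, 0.5, 0.5]], stage="PC1")
        with pytest.raises(g.GCodeQCError):
            g.shell_filter(pc1, vmap)

    def test_wrong_stage_rejected(self, small_box_stages):
        pc4, vmap, _ = small_box_stages
        with pytest.raises(StageError):
            g.shell_filter(pc4, vmap)


class TestXYCorrect:
    def _map_infill_above_y(self, y_thresh=2.0):
        # SHELL band around y = y_thresh, INTERIOR above, EMPTY below
        def labeler(i, j, k):
            y = (j + 0.5) * 0.1
            if y < y_thresh - 0.15:
                return EMPTY
            if y < y_thresh + 0.15:
                return SHELL
            return INTERIOR

        return _flat_map(labeler)

    def test_perimeter_offsets_away_from_infill(self):
        # wall along X at y=2.0 with infill on +Y: the -Y candidate is kept
        vmap = self._map_infill_above_y(2.0)
        pc2 = _line_cloud([[1.0, 2.0, 0.25], [2.0, 2.0, 0.25], [3.0, 2.0, 0.25]])
        pc3 = g.xy_correct(pc2, vmap, W)
        assert pc3.stage == "PC3"
        assert len(pc3) == 3
        np.testing.assert_allclose(pc3.points[:, 1], 2.0 - W / 2)
        np.testing.assert_allclose(pc3.points[:, 2], 0.25)   # Z unchanged
        assert set(pc3.verdict) <= {VERDICT_KEEP_PRIME, VERDICT_KEEP_DOUBLE}

    def test_single_line_keeps_both(self):
        vmap = _flat_map(
            lambda i, j, k: SHELL if abs((j + 0.5) * 0.1 - 2.0) < 0.3 else EMPTY
        )
        pc2 = _line_cloud([[1.0, 2.0, 0.25], [2.0, 2.0, 0.25]])
        pc3 = g.xy_correct(pc2, vmap, W)
        assert len(pc3) == 4
        assert (pc3.verdict == VERDICT_BOTH).all()
        ys = np.sort(np.unique(np.round(pc3.points[:, 1], 6)))
        np.testing.assert_allclose(ys, [2.0 - W / 2, 2.0 + W / 2])

    def test_both_in_infill_drops_with_diagnostic(self):
        # points at y=3 are surrounded by infill (both candidates interior,
        # dropped and counted); the point at y=0.5 survives as single line
        vmap = _flat_map(
            lambda i, j, k: SHELL if (j + 0.5) * 0.1 < 1.0 else INTERIOR
        )
        pc2 = _line_cloud(
            [[1.0, 0.5, 0.25], [1.0, 3.0, 0.25], [2.0, 3.0, 0.25]]
        )
        pc3 = g.xy_correct(pc2, vmap, W)
        assert pc3.stats["n_error_drop"] == 2
        assert len(pc3) == 2                      # the single-line pair
        assert (pc3.verdict == VERDICT_BOTH).all()

    def test_all_points_in_infill_is_an_error(self):
        vmap = _flat_map(lambda i, j, k: INTERIOR)
        pc2 = _line_cloud([[1.0, 2.0, 0.25], [2.0, 2.0, 0.25]])
        with pytest.raises(g.GCodeQCError):
            g.xy_correct(pc2, vmap, W)

    def test_vertical_tangent_skipped_with_warning(self):
        vmap = self._map_infill_above_y()
        pc2 = _line_cloud(
            [[1.0, 2.0, 0.25], [2.0, 2.0, 0.25]],
            tangents=[[0, 0, 1], [1, 0, 0]],
        )
        with pytest.warns(UserWarning, match="tangent"):
            pc3 = g.xy_correct(pc2, vmap, W)
        assert len(pc3) == 1
        assert pc3.stats["n_skipped_tangent"] == 1

    def test_offset_magnitude_is_half_line_width(self):
        p1, p2 = correct.offset_candidates([5.0, 0.0, 0.2], [1.0, 0.0, 0.0], W)
        np.testing.assert_allclose(p1, [5.0, 0.2, 0.2])
        np.testing.assert_allclose(p2, [5.0, -0.2, 0.2])

    def test_stage_machine_forbids_double_application(self, small_box_stages):
        pc4, vmap, _ = small_box_stages
        with pytest.raises(StageError):
            g.xy_correct(pc4, vmap, W)


class TestZCorrect:
    def _wall_map(self):
        # occupied slab z in [0, 0.6): column voxels 0..5 occupied
        def labeler(i, j, k):
            return INTERIOR if k < 6 else EMPTY

        return _flat_map(labeler, dims=(20, 20, 12))

    def test_side_point_moves_down_one_layer(self):
        vmap = self._wall_map()
        pc3 = _line_cloud([[1.0, 1.0, 0.4], [1.5, 1.0, 0.4]], stage="PC3")
        pc4 = g.z_correct(pc3, vmap, H)
        assert pc4.stage == "PC4"
        np.testing.assert_allclose(pc4.points[:, 2], 0.2)

    def test_top_point_stays_after_down_then_up(self):
        vmap = self._wall_map()
        pc3 = _line_cloud([[1.0, 1.0, 0.55], [1.5, 1.0, 0.55]], stage="PC3")
        pc4 = g.z_correct(pc3, vmap, H)   # voxel above (k=6) is EMPTY
        np.testing.assert_allclose(pc4.points[:, 2], 0.55)
        assert pc4.superior.all()

    def test_below_grid_clamped_with_warning(self):
        vmap = self._wall_map()
        pc3 = _line_cloud([[1.0, 1.0, 0.1], [1.5, 1.0, 0.1]], stage="PC3")
        with pytest.warns(UserWarning, match="clamped"):
            pc4 = g.z_correct(pc3, vmap, H)
        np.testing.assert_allclose(pc4.points[:, 2], 0.0)

    def test_stage_machine(self, small_box_stages):
        pc4, vmap, _ = small_box_stages
        with pytest.raises(StageError):
            g.z_correct(pc4, vmap, H)


class TestOnFixtures:
    def test_pc3_never_in_interior_voxel(self, small_box_toolpath):
        cfg = g.RunConfig()
        tp = small_box_toolpath
        pc1 = extract_centerline_points(tp, spacing=cfg.spacing)
        vmap = g.classify_labels(g.voxelize(pc1, W, H, cfg.voxel_size))
        pc2 = g.shell_filter(pc1, vmap, w=W, h=H)
        pc3 = g.xy_correct(pc2, vmap, W)
        assert not g.is_infill(pc3.points, vmap).any()

    def test_ngon_perimeter_offset_radius(self):
        # regular 64-gon cylinder: corrected outer-perimeter points lie one
        # half line width outside the perimeter centerline ring, i.e. back
        # on the model surface (outward-offset correctness on curvature)
        R = 6.0
        n = 64
        scene = g.compose_scene(g.make_ngon_cylinder(R, n, 2.0))
        center_ref = scene.model_mesh.bounds.mean(axis=0)
        res = g.run_scene(scene)
        pcm = res.pc4_model
        mid = (pcm.points[:, 2] > 0.5) & (pcm.points[:, 2] < 1.5)
        keep = np.isin(pcm.verdict, (VERDICT_KEEP_PRIME, VERDICT_KEEP_DOUBLE))
        pts = pcm.points[mid & keep]
        r = np.linalg.norm(pts[:, :2] - center_ref[:2], axis=1)
        # analytic mean radius of points uniform on the centerline ring,
        # shifted outward by w/2
        a_model = R * np.cos(np.pi / n)
        a_center = a_model - W / 2
        r_center_vertex = a_center / np.cos(np.pi / n)
        mean_centerline = a_center + (r_center_vertex - a_center) / 3.0
        assert abs(r.mean() - (mean_centerline + W / 2)) <= 0.02

    def test_deposition_plane_alignment(self, small_box_stages):
        pc4, _, _ = small_box_stages
        frac = deposition_plane_fraction(pc4.points[:, 2], H)
        assert frac >= 99.9
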