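"""Voxel label maps: rasterization, classification, marching cubes."""

from collections import deque

import numpy as np
import pytest

import gcodeqc as g
from gcodeqc import voxel
from gcodeqc.errors import EmptyCloudError, ResolutionError
from gcodeqc.gcode import ProcessMeta, extract_centerline_points, parse_gcode
from gcodeqc.voxel import EMPTY, INTERIOR, SHELL, VoxelLabelMap


def _map_from_occ(occ, voxel_size=0.1):
    labels = np.where(occ, np.uint8(INTERIOR), np.uint8(EMPTY))
    return VoxelLabelMap(origin=np.zeros(3), voxel_size=voxel_size, labels=labels)


def _block_map(n, margin=2):
    dims = n + 2 * margin
    occ = np.zeros((dims, dims, dims), dtype=bool)
    occ[margin:-margin, margin:-margin, margin:-margin] = True
    return _map_from_occ(occ)


def _exterior_bfs(occ):
    """Brute-force 6-connected flood fill from the grid boundary."""
    nx, ny, nz = occ.shape
    ext = np.zeros_like(occ)
    q = deque()
    for idx in np.ndindex(occ.shape):
        i, j, k = idx
        if (i in (0, nx - 1) or j in (0, ny - 1) or k in (0, nz - 1)) and not occ[idx]:
            if not ext[idx]:
                ext[idx] = True
                q.append(idx)
    while q:
        i, j, k = q.popleft()
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            a, b, c = i + di, j + dj, k + dk
            if 0 <= a < nx and 0 <= b < ny and 0 <= c < nz:
                if not occ[a, b, c] and not ext[a, b, c]:
                    ext[a, b, c] = True
                    q.append((a, b, c))
    return ext


class TestVoxelize:
    def _pc1(self, text, spacing=0.05):
        tp = parse_gcode(text, ProcessMeta(0.2, 0.4))
        return extract_centerline_points(tp, spacing=spacing)

    def test_single_segment_footprint(self):
        pc1 = self._pc1("G90\nM82\nG1 X0 Y0 Z0.2 E0\nG1 X10 E0.5")
        vmap = g.voxelize(pc1, w=0.4, h=0.2, voxel_size=0.1)
        occ = vmap.occupied
        idx = np.argwhere(occ)
        ext = (idx.max(axis=0) - idx.min(axis=0) + 1) * vmap.voxel_size
        assert abs(ext[0] - 10.4) <= 0.2 + 1e-9
        assert abs(ext[1] - 0.4) <= 0.2 + 1e-9
        assert ext[2] == pytest.approx(0.2)       # one layer = 2 voxels thick

    def test_empty_margin_surrounds_occupancy(self):
        pc1 = self._pc1("G90\nM82\nG1 X0 Y0 Z0.2 E0\nG1 X5 Y5 E0.5")
        vmap = g.voxelize(pc1, w=0.4, h=0.2, voxel_size=0.1)
        occ = vmap.occupied
        assert not occ[0].any() and not occ[-1].any()
        assert not occ[:, 0].any() and not occ[:, -1].any()
        assert not occ[:, :, 0].any() and not occ[:, :, -1].any()

    def test_no_pc1_point_in_empty_voxel(self, small_box_stages, small_box_toolpath):
        _, vmap, _ = small_box_stages
        pc1 = extract_centerline_points(small_box_toolpath, spacing=0.05)
        labels = vmap.label_at(pc1.points)
        assert (labels != EMPTY).all()

    def test_voxel_size_precondition(self):
        pc1 = self._pc1("G90\nM82\nG1 X0 Y0 Z0.2 E0\nG1 X10 E0.5")
        with pytest.raises(ValueError, match="voxel_size"):
            g.voxelize(pc1, w=0.4, h=0.2, voxel_size=0.15)

    def test_empty_cloud_rejected(self):
        from gcodeqc.cloud import StagedPointCloud

        empty = StagedPointCloud(
            np.zeros((0, 3)), np.zeros(0), np.zeros(0), np.zeros(0),
            np.zeros(0), np.zeros((0, 3)),
        )
        with pytest.raises(EmptyCloudError):
            g.voxelize(empty, w=0.4, h=0.2)

    def test_cell_budget(self):
        pc1 = self._pc1("G90\nM82\nG1 X0 Y0 Z0.2 E0\nG1 X10 E0.5")
        with pytest.raises(ResolutionError, match="voxel_size"):
            g.voxelize(pc1, w=0.4, h=0.2, voxel_size=0.1, cell_budget=1000)

    def test_solid_box_has_no_cavities(self, small_box_stages):
        # 100% infill fixture: flood fill finds no enclosed empty region
        _, vmap, _ = small_box_stages
        occ = vmap.occupied
        ext = voxel.exterior_empty_mask(vmap)
        assert ((~occ) == ext).all()


class TestClassify:
    def test_five_cube_crust(self):
        vmap = g.classify_labels(_block_map(5))
        assert (vmap.labels == SHELL).sum() == 5**3 - 3**3   # 98
        assert (vmap.labels == INTERIOR).sum() == 3**3       # 27

    def test_single_voxel_is_shell(self):
        occ = np.zeros((5, 5, 5), dtype=bool)
        occ[2, 2, 2] = True
        vmap = g.classify_labels(_map_from_occ(occ))
        assert (vmap.labels == SHELL).sum() == 1
        assert (vmap.labels == INTERIOR).sum() == 0

    def test_hollow_box_inner_walls_stay_interior(self):
        # 9^3 box with 5^3 cavity: the cavity is not exterior-connected, so
        # voxels facing it are INTERIOR, verified against a BFS oracle
        occ = np.zeros((13, 13, 13), dtype=bool)
        occ[2:11, 2:11, 2:11] = True
        occ[4:9, 4:9, 4:9] = False
        vmap = g.classify_labels(_map_from_occ(occ))
        ext = _exterior_bfs(occ)
        inner_wall = occ & ~ext
        inner_wall[occ] = False
        # voxels adjacent to the cavity only:
        cavity_adjacent = occ.copy()
        cavity_adjacent[:] = False
        cavity_adjacent[3:10, 3:10, 3:10] = occ[3:10, 3:10, 3:10]
        shell = vmap.labels == SHELL
        assert not shell[4:9, 4:9, 4:9].any()
        assert (vmap.labels[3, 4:9, 4:9] == INTERIOR).all()  # inner wall face

    def test_idempotent(self):
        vmap = g.classify_labels(_block_map(6))
        again = g.classify_labels(vmap)
        assert np.array_equal(vmap.labels, again.labels)

    def test_shell_union_interior_is_occupancy(self, small_box_stages):
        _, vmap, _ = small_box_stages
        occ = vmap.occupied
        assert np.array_equal(occ, (vmap.labels == SHELL) | (vmap.labels == INTERIOR))

    def test_exterior_oracle_on_random_grids(self):
        rng = np.random.default_rng(7)
        for _ in range(3):
            occ = np.zeros((20, 18, 16), dtype=bool)
            for _ in range(6):  # random boxes, possibly enclosing voids
                lo = rng.integers(1, 8, size=3)
                hi = lo + rng.integers(3, 9, size=3)
                occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
            vmap = _map_from_occ(occ)
            assert np.array_equal(voxel.exterior_empty_mask(vmap), _exterior_bfs(occ))


class TestInfillQuery:
    def test_center_of_block_is_infill(self):
        vmap = g.classify_labels(_block_map(5))
        center = vmap.index_to_center([[4, 4, 4]])[0]
        assert g.is_infill(center, vmap)[0]

    def test_point_outside_is_not_infill(self):
        vmap = g.classify_labels(_block_map(5))
        assert not g.is_infill([-1.0, -1.0, -1.0], vmap)[0]

    def test_shell_voxel_is_not_infill(self):
        vmap = g.classify_labels(_block_map(5))
        shell_center = vmap.index_to_center([[2, 4, 4]])[0]
        assert vmap.label_at(shell_center[None])[0] == SHELL
        assert not g.is_infill(shell_center, vmap)[0]

    def test_half_open_voxel_membership(self):
        vmap = g.classify_labels(_block_map(5))
        # a point exactly on a voxel boundary belongs to the upper voxel
        boundary = vmap.origin + np.array([0.2, 0.25, 0.25])
        idx = vmap.world_to_index(boundary[None])[0]
        assert idx[0] == 2


class TestMarchingCubes:
    def test_single_voxel_surface(self):
        occ = np.zeros((5, 5, 5), dtype=bool)
        occ[2, 2, 2] = True
        mesh = g.marching_cubes_surface(_map_from_occ(occ))
        assert mesh.is_watertight
        assert mesh.euler_number == 2                      # genus 0
        assert 0.0 < mesh.volume <= 0.1**3 + 1e-9

    def test_ten_cube_volume(self):
        mesh = g.marching_cubes_surface(_block_map(10))
        assert mesh.is_watertight
        assert abs(mesh.volume - 1.0) / 1.0 <= 0.15

    def test_volume_tracks_occupancy_within_one_shell(self, small_box_stages):
        _, vmap, _ = small_box_stages
        mesh = g.marching_cubes_surface(vmap)
        occ_vol = vmap.occupied.sum() * vmap.voxel_size**3
        shell_vol = (vmap.labels == SHELL).sum() * vmap.voxel_size**3
        assert mesh.is_watertight
        assert abs(mesh.volume - occ_vol) <= shell_vol

    def test_empty_map_rejected(self):
        occ = np.zeros((5, 5, 5), dtype=bool)
        with pytest.raises(EmptyCloudError):
            g.marching_cubes_surface(_map_from_occ(occ))


def test_quantization_bound_per_axis():
    # any point's per-axis distance to its containing-voxel center is at
    # most half the voxel size (0.05 mm at the default 0.10 mm grid)
    vmap = _block_map(5)
    rng = np.random.default_rng(3)
    pts = rng.uniform(0.0, 0.9, size=(5000, 3))
    idx = vmap.world_to_index(pts)
    centers = vmap.index_to_center(idx)
    assert np.abs(pts - centers).max() <= 0.05 + 1e-12
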