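"""Voxel label maps: toolpath rasterization, shell/infill classification,
and marching-cubes surface extraction.

The centerline cloud is rasterized onto a regular grid (default 0.10 mm) and
dilated by the material footprint of a deposited bead — ``±w/2`` laterally
and one layer height downward from the nozzle plane — so that occupied
voxels represent deposited material rather than bare centerlines.  A
morphological closing with a radius-1 ball then fuses any remaining small
voids between adjacent extrusion lines.

Occupied voxels 26-adjacent to the exterior-connected empty region form the
SHELL; all other occupied voxels are INTERIOR (infill / inner perimeters).
Complementary connectivity is used: 26 for occupied adjacency, 6 for the
exterior empty region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cloud import StagedPointCloud
from .errors import EmptyCloudError, GCodeQCError, ResolutionError

EMPTY = 0
INTERIOR = 1
SHELL = 2

_STRUCT_6 = ndimage.generate_binary_structure(3, 1)
_STRUCT_26 = ndimage.generate_binary_structure(3, 3)


@dataclass
class VoxelLabelMap:
    """Regular grid labelling space as EMPTY / INTERIOR / SHELL.

    ``origin`` is the world coordinate of the low corner of voxel
    ``(0, 0, 0)``; voxel membership is half-open, ``[lo, hi)`` per axis.
    """

    origin: np.ndarray
    voxel_size: float
    labels: np.ndarray          # (nx, ny, nz) uint8
    classified: bool = False

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def occupied(self) -> np.ndarray:
        return self.labels != EMPTY

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Containing-voxel indices (half-open intervals, floor rule)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.floor((pts - self.origin) / self.voxel_size).astype(np.int64)

    def index_to_center(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + (np.asarray(idx, dtype=float) + 0.5) * self.voxel_size

    def in_bounds(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(idx)
        dims = np.asarray(self.dims)
        return np.all((idx >= 0) & (idx < dims), axis=1)

    def label_at(self, points: np.ndarray) -> np.ndarray:
        """Per-point label; points outside the grid are EMPTY."""
        idx = self.world_to_index(points)
        ok = self.in_bounds(idx)
        out = np.full(len(idx), EMPTY, dtype=np.uint8)
        ii = idx[ok]
        out[ok] = self.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out


def _footprint_offsets(w: float, h: float, voxel_size: float) -> np.ndarray:
    """Integer voxel offsets covered by a bead: lateral disc of radius w/2,
    vertical span one layer height below the nozzle plane."""
    r_lat = int(np.floor(w / 2.0 / voxel_size + 1e-9))
    # bead thickness h including the sampled point's own voxel, extending down
    n_dn = max(1, int(np.round(h / voxel_size)))
    offs = []
    for dx in range(-r_lat, r_lat + 1):
        for dy in range(-r_lat, r_lat + 1):
            if (dx * voxel_size) ** 2 + (dy * voxel_size) ** 2 <= (w / 2) ** 2 + 1e-12:
                for dz in range(-(n_dn - 1), 1):
                    offs.append((dx, dy, dz))
    return np.asarray(offs, dtype=np.int64)


def voxelize(
    pc1: StagedPointCloud,
    w: float,
    h: float,
    voxel_size: float = 0.10,
    cell_budget: int = 1_500_000_000,
) -> VoxelLabelMap:
    """Rasterize a PC1 cloud into a binary label map (occupied = INTERIOR
    until :func:`classify_labels` runs).

    Preconditions: ``voxel_size <= min(w, h) / 2`` so the bead footprint
    spans at least two voxels and sampling at ``voxel_size / 2`` cannot skip
    cells.
    """
    if len(pc1) == 0:
        raise EmptyCloudError("cannot voxelize an empty cloud")
    if voxel_size > min(w, h) / 2.0 + 1e-12:
        raise ValueError(
            f"voxel_size {voxel_size} must be <= min(w, h)/2 = {min(w, h) / 2}"
        )
    offs = _footprint_offsets(w, h, voxel_size)
    r_lat = int(-offs[:, 0].min())
    n_dn = int(-offs[:, 2].min())
    # margin: footprint + closing ball (1) + guaranteed empty border (1)
    lo_margin = np.array([r_lat + 2, r_lat + 2, n_dn + 2])
    hi_margin = np.array([r_lat + 2, r_lat + 2, 2])

    pmin = pc1.points.min(axis=0)
    pmax = pc1.points.max(axis=0)
    # origin snapped to the voxel lattice for run-to-run reproducibility
    origin = (np.floor(pmin / voxel_size) - lo_margin) * voxel_size
    dims = (
        np.ceil((pmax - origin) / voxel_size).astype(np.int64) + hi_margin + 1
    )
    if int(np.prod(dims)) > cell_budget:
        suggested = voxel_size * (np.prod(dims) / cell_budget) ** (1 / 3)
        raise ResolutionError(
            f"grid {tuple(dims)} exceeds cell budget {cell_budget}; "
            f"try voxel_size >= {suggested:.3f} mm"
        )

    occ = np.zeros(tuple(dims), dtype=bool)
    idx = np.floor((pc1.points - origin) / voxel_size).astype(np.int64)
    occ[idx[:, 0], idx[:, 1], idx[:, 2]] = True

    occ = _dilate_by_offsets(occ, offs)
    occ = ndimage.binary_closing(occ, structure=_STRUCT_26)

    labels = np.where(occ, np.uint8(INTERIOR), np.uint8(EMPTY))
    return VoxelLabelMap(origin=origin, voxel_size=voxel_size, labels=labels)


def _dilate_by_offsets(occ: np.ndarray, offs: np.ndarray) -> np.ndarray:
    """Union of integer shifts of ``occ`` — explicit, order-independent
    dilation by an arbitrary (possibly asymmetric) footprint."""
    out = np.zeros_like(occ)
    nx, ny, nz = occ.shape
    for dx, dy, dz in offs:
        src = [slice(max(0, -d), min(s, s - d)) for d, s in ((dx, nx), (dy, ny), (dz, nz))]
        dst = [slice(max(0, d), min(s, s + d)) for d, s in ((dx, nx), (dy, ny), (dz, nz))]
        out[tuple(dst)] |= occ[tuple(src)]
    return out


def exterior_empty_mask(vmap: VoxelLabelMap) -> np.ndarray:
    """Empty voxels 6-connected to the grid boundary."""
    empty = ~vmap.occupied
    lab, _ = ndimage.label(empty, structure=_STRUCT_6)
    border = np.unique(
        np.concatenate([
            lab[0].ravel(), lab[-1].ravel(),
            lab[:, 0].ravel(), lab[:, -1].ravel(),
            lab[:, :, 0].ravel(), lab[:, :, -1].ravel(),
        ])
    )
    border = border[border != 0]
    return np.isin(lab, border)


def classify_labels(vmap: VoxelLabelMap) -> VoxelLabelMap:
    """Split occupied voxels into SHELL (26-adjacent to the exterior empty
    region) and INTERIOR.  Idempotent."""
    occ = vmap.occupied
    exterior = exterior_empty_mask(vmap)
    near_ext = ndimage.binary_dilation(exterior, structure=_STRUCT_26)
    labels = np.where(occ, np.uint8(INTERIOR), np.uint8(EMPTY))
    labels[occ & near_ext] = SHELL
    return VoxelLabelMap(
        origin=vmap.origin, voxel_size=vmap.voxel_size,
        labels=labels, classified=True,
    )


def shell_reach_mask(vmap: VoxelLabelMap, w: float, h: float) -> np.ndarray:
    """Voxels whose deposited bead would touch the SHELL crust.

    The label map is built from *dilated* bead footprints, so the outer
    crust lies up to ``w/2`` away from the centerline a point was sampled
    on.  A centerline point belongs to the printed shell when any voxel of
    its own bead footprint (disc of radius ``w/2``, one layer height tall)
    is a SHELL voxel; this mask marks every voxel with that property.
    """
    if not vmap.classified:
        raise GCodeQCError("label map must be classified first")
    shell = vmap.labels == SHELL
    # v is shell-reaching iff v + o is SHELL for some footprint offset o,
    # i.e. v lies in the dilation of the crust by the reflected footprint
    return _dilate_by_offsets(shell, -_footprint_offsets(w, h, vmap.voxel_size))


def vertical_shell_reach(vmap: VoxelLabelMap, h: float) -> np.ndarray:
    """Voxels whose vertical bead column (own voxel plus ``h`` worth of
    voxels below) contains a SHELL voxel.

    This is the footprint-aware notion used by the XY infill decision: a
    nozzle position deposits a one-layer-tall column of material, and that
    position counts as surface (not infill) when any of that column is
    crust.  The lateral disc is deliberately excluded here — including it
    overreaches at concave junctions (e.g. where a step wall meets its
    shelf) and misclassifies buried points as surface.
    """
    if not vmap.classified:
        raise GCodeQCError("label map must be classified first")
    n_dn = max(1, int(np.round(h / vmap.voxel_size)))
    col = np.asarray([(0, 0, -dz) for dz in range(n_dn)], dtype=np.int64)
    return _dilate_by_offsets(vmap.labels == SHELL, -col)


def is_infill(
    points: np.ndarray,
    vmap: VoxelLabelMap,
    h: float | None = None,
) -> np.ndarray:
    """True where a point lies in the infill (occupied but not part of the
    outer shell); points in SHELL, EMPTY or outside the grid are not infill.

    With the layer height given (footprint-dilated maps), "part of the
    outer shell" means the point's vertical bead column touches the SHELL
    crust; without it, the point's own voxel label decides.
    """
    if not vmap.classified:
        raise GCodeQCError("label map must be classified before infill queries")
    if h is None:
        return vmap.label_at(points) == INTERIOR
    return infill_with_reach(points, vmap, vertical_shell_reach(vmap, h))


def infill_with_reach(
    points: np.ndarray, vmap: VoxelLabelMap, reach: np.ndarray
) -> np.ndarray:
    """Footprint-aware infill test against a precomputed shell-reach mask."""
    idx = vmap.world_to_index(points)
    ok = vmap.in_bounds(idx)
    out = np.zeros(len(idx), dtype=bool)
    ii = idx[ok]
    occupied = vmap.labels[ii[:, 0], ii[:, 1], ii[:, 2]] != EMPTY
    out[ok] = occupied & ~reach[ii[:, 0], ii[:, 1], ii[:, 2]]
    return out


def marching_cubes_surface(vmap: VoxelLabelMap):
    """Extract the iso-0.5 surface of the binary occupancy as a watertight,
    outward-oriented triangle mesh in world millimetres."""
    import trimesh
    from skimage import measure

    occ = vmap.occupied
    if not occ.any():
        raise EmptyCloudError("label map has no occupied voxels")
    verts, faces, _, _ = measure.marching_cubes(
        occ.astype(np.float32), level=0.5,
        spacing=(vmap.voxel_size,) * 3, method="lewiner",
    )
    # grid samples sit at voxel centers
    verts = verts + vmap.origin + 0.5 * vmap.voxel_size
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        raise GCodeQCError("marching-cubes surface unexpectedly not watertight")
    return mesh


def export_labels_nifti(vmap: VoxelLabelMap, path) -> None:
    """Debug export of the label map as a NIfTI volume (x, y, z axis order,
    mm spacing) for visual inspection."""
    import nibabel as nib

    affine = np.diag([vmap.voxel_size] * 3 + [1.0])
    affine[:3, 3] = vmap.origin + 0.5 * vmap.voxel_size
    nib.save(nib.Nifti1Image(vmap.labels.astype(np.uint8), affine), str(path))
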