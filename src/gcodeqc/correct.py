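"""Stage corrections: shell filtering (PC2), XY nozzle-radius offset (PC3)
and Z deposition-plane correction (PC4).

The G-code nozzle centerline is not the printed surface: the bead extends
``w/2`` laterally beyond the centerline and one layer height *below* the
commanded nozzle plane.  The XY correction offsets each shell point by
``w/2`` along the in-plane normal of its local tangent, using the voxel
label map to decide which of the two candidate directions points away from
the infill:

=====================  =====================  =======================
P' (``P + v1``)        P'' (``P + v2``)       outcome
=====================  =====================  =======================
in infill              in infill              no point kept (error)
in infill              not in infill          P'' kept
not in infill          in infill              P' kept
not in infill          not in infill          both kept (single line)
=====================  =====================  =======================

The Z correction moves every point down by the layer height; points whose
voxel has empty space directly above belong to the superior edge of the
object (the top surface the nozzle plane already describes) and are moved
back up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cloud import (
    VERDICT_BOTH,
    VERDICT_ERROR,
    VERDICT_KEEP_DOUBLE,
    VERDICT_KEEP_PRIME,
    StagedPointCloud,
)
from .errors import EmptyCloudError
from .voxel import EMPTY, SHELL, VoxelLabelMap, is_infill

_TANGENT_TOL = 1e-9


@dataclass(frozen=True)
class OffsetCandidatePair:
    """The two XY offset candidates of a single point (debug/QC helper)."""

    base: np.ndarray
    prime: np.ndarray         # P'  = P + v1
    double_prime: np.ndarray  # P'' = P + v2 = P - v1
    verdict: int

    @property
    def offset_magnitude(self) -> float:
        return float(np.linalg.norm(self.prime - self.base))


def offset_candidates(point, tangent, w: float) -> tuple[np.ndarray, np.ndarray]:
    """In-plane unit normals to ``tangent`` scaled to ``w/2``, applied to
    ``point``; both candidates share the point's Z."""
    point = np.asarray(point, dtype=float)
    t = np.asarray(tangent, dtype=float)
    n = np.array([-t[1], t[0], 0.0])
    norm = np.linalg.norm(n)
    if norm < _TANGENT_TOL:
        raise ValueError("tangent has no in-plane component")
    n = n / norm * (w / 2.0)
    return point + n, point - n


def shell_filter(
    pc1: StagedPointCloud,
    vmap: VoxelLabelMap,
    w: float | None = None,
    h: float | None = None,
) -> StagedPointCloud:
    """Retain exactly the PC1 points belonging to the outer shell.

    When the bead dimensions ``w``/``h`` are given (the map was built from
    dilated bead footprints), a centerline point is a shell point iff its
    own bead footprint touches a SHELL voxel; without them the point's
    containing voxel must itself be SHELL.  Links are re-threaded across
    removed points within the same contiguous path; a point landing in an
    EMPTY voxel (numerical stray) is removed with a warning.
    """
    pc1.require_stage("PC1")
    labels = vmap.label_at(pc1.points)
    n_empty = int((labels == EMPTY).sum())
    if n_empty:
        warnings.warn(
            f"{n_empty} centerline points fell in EMPTY voxels and were dropped",
            stacklevel=2,
        )
    if w is not None and h is not None:
        from .voxel import shell_reach_mask

        reach = shell_reach_mask(vmap, w, h)
        idx = vmap.world_to_index(pc1.points)
        ok = vmap.in_bounds(idx)
        mask = np.zeros(len(pc1), dtype=bool)
        ii = idx[ok]
        mask[ok] = reach[ii[:, 0], ii[:, 1], ii[:, 2]]
        mask &= labels != EMPTY
    else:
        mask = labels == SHELL
    if not mask.any():
        raise EmptyCloudError("shell filter removed every point")
    out = pc1.select(mask, stage="PC2")
    out.stats = {"n_input": len(pc1), "n_kept": int(mask.sum()), "n_empty": n_empty}
    return out


def xy_correct(
    pc2: StagedPointCloud,
    vmap: VoxelLabelMap,
    w: float,
    h: float | None = None,
) -> StagedPointCloud:
    """Apply the ``-w/2`` nozzle-radius offset with infill decision logic.

    Each output point records a verdict and the index of its base point.
    Points whose tangent has no in-plane component (vertical or degenerate)
    are skipped with a warning; points whose both candidates fall in the
    infill are dropped and counted.  With ``h`` given, the infill test is
    footprint-aware (consistent with the shell filter on dilated maps).
    """
    pc2.require_stage("PC2")
    if w <= 0:
        raise ValueError("line width must be positive")
    t = pc2.tangent
    normal = np.stack([-t[:, 1], t[:, 0], np.zeros(len(pc2))], axis=1)
    nrm = np.linalg.norm(normal, axis=1)
    usable = nrm > _TANGENT_TOL
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} points without usable in-plane tangent skipped",
            stacklevel=2,
        )
    normal[usable] /= nrm[usable, None]
    normal *= w / 2.0

    p_prime = pc2.points + normal
    p_double = pc2.points - normal
    if h is not None:
        from .voxel import infill_with_reach, vertical_shell_reach

        reach = vertical_shell_reach(vmap, h)
        in1 = infill_with_reach(p_prime, vmap, reach)
        in2 = infill_with_reach(p_double, vmap, reach)
    else:
        in1 = is_infill(p_prime, vmap)
        in2 = is_infill(p_double, vmap)

    verdict = np.full(len(pc2), VERDICT_ERROR, dtype=np.int64)
    verdict[in1 & ~in2] = VERDICT_KEEP_DOUBLE
    verdict[~in1 & in2] = VERDICT_KEEP_PRIME
    verdict[~in1 & ~in2] = VERDICT_BOTH
    verdict[~usable] = VERDICT_ERROR  # unusable tangents contribute nothing

    keep_prime = usable & np.isin(verdict, (VERDICT_KEEP_PRIME, VERDICT_BOTH))
    keep_double = usable & np.isin(verdict, (VERDICT_KEEP_DOUBLE, VERDICT_BOTH))
    # emit P' then P'' per base point, bases in G-code order
    cand = np.stack([p_prime, p_double], axis=1).reshape(-1, 3)
    emit = np.stack([keep_prime, keep_double], axis=1).reshape(-1)
    if not emit.any():
        raise EmptyCloudError("XY correction dropped every point")
    base = np.repeat(np.arange(len(pc2), dtype=np.int64), 2)[emit]

    from .cloud import _chain_links

    path = pc2.path_id[base]
    prev, nxt = _chain_links(path)
    out = StagedPointCloud(
        cand[emit], prev, nxt, pc2.layer[base], path,
        pc2.tangent[base], stage="PC3", role=pc2.role,
        base_idx=base, verdict=verdict[base],
    )
    out.stats = {
        "n_input": len(pc2),
        "n_error_drop": int((verdict[usable] == VERDICT_ERROR).sum()),
        "n_skipped_tangent": int((~usable).sum()),
        "n_single_line": int((verdict == VERDICT_BOTH).sum()),
    }
    return out


def z_correct(pc3: StagedPointCloud, vmap: VoxelLabelMap, h: float) -> StagedPointCloud:
    """Move points down one layer height; raise superior-edge points back up.

    A point is part of the superior edge when the voxel directly above its
    pre-shift voxel is EMPTY (no material deposited above): there the nozzle
    plane itself is the printed top surface.
    """
    pc3.require_stage("PC3")
    if h <= 0:
        raise ValueError("layer height must be positive")
    idx = vmap.world_to_index(pc3.points)
    above = idx + np.array([0, 0, 1])
    ok = vmap.in_bounds(above)
    lbl_above = np.full(len(pc3), EMPTY, dtype=np.uint8)
    ii = above[ok]
    lbl_above[ok] = vmap.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
    superior = lbl_above == EMPTY

    pts = pc3.points.copy()
    pts[:, 2] -= h
    pts[superior, 2] += h

    floor_z = vmap.origin[2]
    below = pts[:, 2] < floor_z
    if below.any():
        warnings.warn(
            f"{int(below.sum())} bottom-layer points clamped to the grid floor",
            stacklevel=2,
        )
        pts[below, 2] = floor_z

    out = StagedPointCloud(
        pts, pc3.prev.copy(), pc3.next.copy(), pc3.layer.copy(),
        pc3.path_id.copy(), pc3.tangent.copy(), stage="PC4", role=pc3.role,
        base_idx=None if pc3.base_idx is None else pc3.base_idx.copy(),
        verdict=None if pc3.verdict is None else pc3.verdict.copy(),
        superior=superior,
    )
    out.stats = {"n_superior_edge": int(superior.sum()), "n_clamped": int(below.sum())}
    return out
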