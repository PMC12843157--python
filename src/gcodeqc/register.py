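"""Calibration-object based rigid registration.

Slicers place the scene in their own build-plate coordinate system, so the
corrected cloud must be registered back onto the reference STL before any
comparison.  A small step-shaped calibration object co-sliced with the model
provides the anchor: the scene is split into its two disconnected components
on the voxel map, the component whose bounding box matches the calibration
dimensions becomes the calibration cloud (PCO), and the remaining points the
model cloud (PCM).  PCO is aligned to the analytic calibration mesh by a
center-of-mass translation followed by rigid ICP (rotation + translation, no
scaling); the resulting transform is then applied to PCM, yielding the
registered model cloud (TPCM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

import trimesh

from .cloud import StagedPointCloud
from .errors import CalibrationNotFoundError, RegistrationError, SplitError
from .metrics import SurfaceDistance
from .transform import RigidTransform
from .voxel import VoxelLabelMap, _STRUCT_26

log = logging.getLogger(__name__)

CO_DIMS = (10.00, 6.25, 8.75)   # calibration-object bounding box, mm (X, Y, Z)


def split_calibration(
    pc: StagedPointCloud,
    vmap: VoxelLabelMap,
    co_dims: tuple[float, float, float] = CO_DIMS,
    tol: float = 0.5,
) -> tuple[StagedPointCloud, StagedPointCloud]:
    """Split a scene cloud into (calibration, model) by voxel connectivity.

    The occupied voxels must form exactly two 26-connected components; the
    component whose axis-aligned bounding box matches ``co_dims`` within
    ``tol`` mm per axis (no axis permutation) is the calibration object.
    Points are assigned to components through a KD-tree over occupied voxel
    centers, so stray points just outside the occupancy still resolve.
    """
    lab, n_comp = ndimage.label(vmap.occupied, structure=_STRUCT_26)
    if n_comp != 2:
        raise SplitError(
            f"expected exactly 2 disconnected components in the scene, found {n_comp}"
        )
    # bead footprint + quantization widen each box by about one line width
    slack = vmap.voxel_size + 0.5  # acceptance slack on top of footprint growth
    matches = []
    boxes = []
    for comp in (1, 2):
        idx = np.argwhere(lab == comp)
        ext = (idx.max(axis=0) - idx.min(axis=0) + 1) * vmap.voxel_size
        boxes.append(ext)
        ok = all(abs(ext[i] - co_dims[i]) <= tol + slack for i in range(3))
        matches.append(ok)
    if matches[0] == matches[1]:
        raise CalibrationNotFoundError(
            "could not identify the calibration object: component boxes "
            f"{np.round(boxes[0], 2)} and {np.round(boxes[1], 2)} vs "
            f"expected {co_dims} (±{tol} mm)"
        )
    co_comp = 1 if matches[0] else 2

    occ_idx = np.argwhere(vmap.occupied)
    tree = cKDTree(vmap.index_to_center(occ_idx))
    _, nearest = tree.query(pc.points, k=1)
    vox = occ_idx[nearest]
    comp_of_point = lab[vox[:, 0], vox[:, 1], vox[:, 2]]

    pco = pc.select(comp_of_point == co_comp).with_role("CALIBRATION")
    pcm = pc.select(comp_of_point != co_comp).with_role("MODEL")
    return pco, pcm


def com_prealign(pco: StagedPointCloud, co_mesh: trimesh.Trimesh) -> RigidTransform:
    """Translate the cloud's point mean onto the mesh's volumetric centroid."""
    if len(pco) == 0:
        raise ValueError("empty calibration cloud")
    t = np.asarray(co_mesh.center_mass) - pco.points.mean(axis=0)
    return RigidTransform.from_translation(t)


def icp_refine(
    pco: StagedPointCloud,
    co_mesh: trimesh.Trimesh,
    init: RigidTransform,
    max_iter: int = 50,
    conv: float = 0.02,
) -> RigidTransform:
    """Rigid ICP of the calibration cloud onto the reference mesh surface.

    Correspondences are point-to-nearest-point-on-triangle (not vertex
    only), with no outlier trimming; each iteration applies the
    least-squares point-to-plane rigid update (distances minimized along
    the pseudo-normal at the closest point), which converges in a handful
    of iterations on clean data.  Iteration stops when the RMS residual
    changes by less than ``conv`` (mm) between iterations or after
    ``max_iter`` iterations; five consecutive residual increases raise a
    divergence error.  The returned transform composes the refinement with
    ``init`` and carries the final residual as ``transform.residual_rms``.
    """
    sd = SurfaceDistance(co_mesh)
    current = init
    pts0 = pco.points
    prev_rms = None
    n_increase = 0
    n_converged = 0
    rms = float("nan")
    for it in range(max_iter):
        pts = current.apply(pts0)
        d, closest, ti, bary = sd.closest(pts)
        rms = float(np.sqrt(np.mean(d * d)))
        log.debug("ICP iteration %d: rms residual %.6f mm", it, rms)
        if prev_rms is not None:
            if rms > prev_rms + 1e-12:
                n_increase += 1
                if n_increase >= 5:
                    raise RegistrationError(
                        f"ICP diverged: residual increased {n_increase} "
                        f"consecutive iterations (rms {rms:.4f} mm)"
                    )
            else:
                n_increase = 0
            # converged once the RMS change stays below conv for two
            # consecutive iterations (a single dip near the noise floor can
            # occur while the transform is still settling)
            if abs(prev_rms - rms) < conv:
                n_converged += 1
                if n_converged >= 2:
                    prev_rms = rms
                    break
            else:
                n_converged = 0
        prev_rms = rms
        normals = sd.pseudo_normal(ti, bary)
        step = _point_to_plane(pts, closest, normals)
        current = step.compose(current)
    out = RigidTransform(current.rotation, current.translation)
    object.__setattr__(out, "residual_rms", prev_rms if prev_rms is not None else rms)
    return out


def _point_to_plane(src: np.ndarray, dst: np.ndarray, normals: np.ndarray) -> RigidTransform:
    """Linearized least-squares rigid update minimizing the residual along
    the surface normal at each correspondence; falls back to the point-to-
    point (Kabsch) solution if the normal system is ill-conditioned."""
    from scipy.spatial.transform import Rotation

    r = np.einsum("ij,ij->i", src - dst, normals)
    J = np.hstack([np.cross(src, normals), normals])    # (n, 6)
    JTJ = J.T @ J
    JTr = J.T @ r
    if np.linalg.cond(JTJ) > 1e12:
        return _kabsch(src, dst)
    x = np.linalg.solve(JTJ, -JTr)
    R = Rotation.from_rotvec(x[:3]).as_matrix()
    return RigidTransform(R, x[3:])


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``src`` onto ``dst``."""
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    H = (src - mu_s).T @ (dst - mu_d)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, mu_d - R @ mu_s)


def register_calibration(
    pco: StagedPointCloud,
    co_mesh: trimesh.Trimesh,
    max_iter: int = 50,
    conv: float = 0.02,
) -> RigidTransform:
    """Center-of-mass pre-alignment followed by ICP refinement."""
    init = com_prealign(pco, co_mesh)
    return icp_refine(pco, co_mesh, init, max_iter=max_iter, conv=conv)


def apply_transform(pcm: StagedPointCloud, t: RigidTransform) -> StagedPointCloud:
    """Map every point through the rigid transform; links, stage and layer
    structure are preserved and the role becomes TPCM."""
    out = StagedPointCloud(
        t.apply(pcm.points),
        pcm.prev.copy(), pcm.next.copy(), pcm.layer.copy(),
        pcm.path_id.copy(), pcm.tangent @ t.rotation.T,
        stage=pcm.stage, role="TPCM",
        base_idx=None if pcm.base_idx is None else pcm.base_idx.copy(),
        verdict=None if pcm.verdict is None else pcm.verdict.copy(),
        superior=None if pcm.superior is None else pcm.superior.copy(),
    )
    return out
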