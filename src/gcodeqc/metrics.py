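"""Surface-deviation and volume metrics against a reference mesh.

The deviation statistics are one-sided: for every point ``a_i`` of the
registered cloud, the nearest point ``p`` on the reference surface is found
and the distance signed by the surface normal at ``p``:

.. math::

    d_i = \\operatorname{sign}((a_i - p) \\cdot n_p)\\, \\lVert a_i - p \\rVert

so points outside the solid are positive and points inside negative.  The
report contains the signed mean (MSD), the RMS, and the signed extrema.
Where the closest point falls on an edge or vertex the face normal is
undefined; the angle-weighted average of the incident triangle normals
(the standard pseudo-normal) keeps the sign continuous there.

Volumes are computed by signed-tetrahedron summation over watertight
meshes; the relative volume difference is
``(V_recon - V_ref) / V_ref * 100`` (negative when the reconstruction is
smaller than the reference).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import trimesh

from .cloud import StagedPointCloud
from .errors import EmptyCloudError, GCodeQCError, NonWatertightError

_FEATURE_TOL = 1e-9
_DEGENERATE_AREA = 1e-12


@dataclass
class DeviationReport:
    """Surface and volume deviation between a reconstruction and its
    reference (all lengths mm, volumes mm^3, relative difference %)."""

    msd: float = float("nan")
    rms: float = float("nan")
    d_min: float = float("nan")
    d_max: float = float("nan")
    d_min_abs: float = float("nan")   # unsigned minimum, for debugging
    n_points: int = 0
    volume_ref: float = float("nan")
    volume_recon: float = float("nan")
    volume_diff: float = float("nan")
    volume_diff_rel: float = float("nan")

    def validate(self) -> None:
        if self.n_points > 0:
            if self.rms + 1e-12 < abs(self.msd):
                raise ValueError("invariant violated: rms < |msd|")
            if not (self.d_min <= self.msd <= self.d_max + 1e-12):
                raise ValueError("invariant violated: d_min <= msd <= d_max")

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def csv_row(self) -> dict:
        return asdict(self)


class SurfaceDistance:
    """Closest-point queries against a triangle mesh.

    Distances to every triangle are evaluated exactly (vectorized over
    point x triangle blocks) and the nearest triangle selected with
    lowest-index tie-breaking, which makes results bit-reproducible and
    directly comparable to a brute-force scan.
    """

    def __init__(self, mesh: trimesh.Trimesh):
        areas = mesh.area_faces
        if (areas < _DEGENERATE_AREA).any():
            raise GCodeQCError(
                f"reference mesh has {int((areas < _DEGENERATE_AREA).sum())} "
                "degenerate triangles; repair it first"
            )
        self.mesh = mesh
        self.tri = mesh.triangles.view(np.ndarray).astype(float)  # (m, 3, 3)
        self.face_normals = mesh.face_normals.view(np.ndarray).astype(float)
        self._vertex_normals = _angle_weighted_vertex_normals(mesh)
        self._edge_normals = _edge_normals(mesh)

    # -- closest-point machinery -------------------------------------------
    def closest(self, points: np.ndarray, chunk_cells: int = 4_000_000):
        """Unsigned distances, closest surface points and triangle indices."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        m = len(self.tri)
        step = max(1, chunk_cells // m)
        dists = np.empty(len(pts))
        closest = np.empty((len(pts), 3))
        tri_idx = np.empty(len(pts), dtype=np.int64)
        bary = np.empty((len(pts), 2))
        for s in range(0, len(pts), step):
            p = pts[s : s + step]
            cp, vw = _closest_point_triangles(p, self.tri)
            d2 = np.einsum("ijk,ijk->ij", cp - p[:, None, :], cp - p[:, None, :])
            j = np.argmin(d2, axis=1)  # first minimum = lowest triangle index
            r = np.arange(len(p))
            dists[s : s + step] = np.sqrt(d2[r, j])
            closest[s : s + step] = cp[r, j]
            tri_idx[s : s + step] = j
            bary[s : s + step] = vw[r, j]
        return dists, closest, tri_idx, bary

    def pseudo_normal(self, tri_idx: np.ndarray, bary: np.ndarray) -> np.ndarray:
        """Outward normal at a closest point: face, edge or vertex normal
        depending on which barycentric feature the point lies on."""
        v, w = bary[:, 0], bary[:, 1]
        u = 1.0 - v - w
        out = self.face_normals[tri_idx].copy()
        faces = self.mesh.faces.view(np.ndarray)
        on_u = u <= _FEATURE_TOL
        on_v = v <= _FEATURE_TOL
        on_w = w <= _FEATURE_TOL
        n_zero = on_u.astype(int) + on_v.astype(int) + on_w.astype(int)
        # vertex features: two barycentric coordinates vanish
        vert_sel = n_zero == 2
        if vert_sel.any():
            corner = np.where(~on_u, 0, np.where(~on_v, 1, 2))
            vids = faces[tri_idx[vert_sel], corner[vert_sel]]
            out[vert_sel] = self._vertex_normals[vids]
        # edge features: exactly one vanishes
        edge_sel = n_zero == 1
        if edge_sel.any():
            for mask, (i0, i1) in ((on_u, (1, 2)), (on_v, (0, 2)), (on_w, (0, 1))):
                sel = edge_sel & mask
                if not sel.any():
                    continue
                f = faces[tri_idx[sel]]
                keys = np.sort(f[:, [i0, i1]], axis=1)
                out[sel] = np.array(
                    [self._edge_normals[tuple(k)] for k in keys]
                )
        norms = np.linalg.norm(out, axis=1)
        return out / np.maximum(norms, 1e-30)[:, None]

    def signed(self, points: np.ndarray) -> np.ndarray:
        """Signed distance for each point (0 exactly on the surface)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d, cp, ti, bary = self.closest(pts)
        n = self.pseudo_normal(ti, bary)
        s = np.sign(np.einsum("ij,ij->i", pts - cp, n))
        s[d == 0.0] = 0.0
        return s * d


def signed_point_mesh_distance(point, mesh: trimesh.Trimesh) -> float:
    """Signed distance of one point to a watertight, outward-oriented mesh."""
    return float(SurfaceDistance(mesh).signed(np.atleast_2d(point))[0])


def surface_metrics(
    tpcm: StagedPointCloud, ref: trimesh.Trimesh, require_role: bool = True
) -> DeviationReport:
    """Table of one-sided surface deviations from a registered cloud."""
    if require_role and tpcm.role != "TPCM":
        raise GCodeQCError(
            f"surface metrics expect a registered cloud (role TPCM), got {tpcm.role}"
        )
    if len(tpcm) == 0:
        raise EmptyCloudError("cannot compute metrics on an empty cloud")
    return surface_metrics_points(tpcm.points, ref)


def surface_metrics_points(points: np.ndarray, ref: trimesh.Trimesh) -> DeviationReport:
    d = SurfaceDistance(ref).signed(points)
    rep = DeviationReport(
        msd=float(d.mean()),
        rms=float(np.sqrt(np.mean(d * d))),
        d_min=float(d.min()),
        d_max=float(d.max()),
        d_min_abs=float(np.abs(d).min()),
        n_points=len(d),
    )
    rep.validate()
    return rep


def is_volume_closed(mesh: trimesh.Trimesh) -> bool:
    """True when the mesh is a closed oriented surface in the integration
    sense: every directed edge is balanced by its reverse.

    This accepts strictly watertight 2-manifolds and also layer-merged
    meshes that retain coincident internal face pairs at slab interfaces
    (those pairs cancel exactly in the signed-tetrahedron volume).
    """
    e = mesh.edges  # directed, one per face corner
    key_fwd = e[:, 0] * (mesh.vertices.shape[0] + 1) + e[:, 1]
    key_rev = e[:, 1] * (mesh.vertices.shape[0] + 1) + e[:, 0]
    fwd, n_fwd = np.unique(key_fwd, return_counts=True)
    rev, n_rev = np.unique(key_rev, return_counts=True)
    return len(fwd) == len(rev) and bool(
        np.array_equal(fwd, rev) and np.array_equal(n_fwd, n_rev)
    )


def _require_watertight(mesh: trimesh.Trimesh, name: str) -> trimesh.Trimesh:
    if not mesh.is_watertight and not is_volume_closed(mesh):
        edges = mesh.edges_sorted
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        boundary = int((counts != 2).sum())
        raise NonWatertightError(
            f"{name} mesh is not watertight ({boundary} non-manifold edges)"
        )
    if mesh.volume < 0:
        mesh = mesh.copy()
        mesh.invert()
    return mesh


def mesh_volume(mesh: trimesh.Trimesh) -> float:
    """Volume by signed-tetrahedron summation; inside-out meshes are
    auto-reoriented, open meshes refused."""
    return float(_require_watertight(mesh, "input").volume)


def volume_difference(
    recon: trimesh.Trimesh, ref: trimesh.Trimesh,
    report: DeviationReport | None = None,
) -> DeviationReport:
    """Fill the volume part of a deviation report."""
    v_recon = mesh_volume(recon)
    v_ref = mesh_volume(ref)
    rep = report if report is not None else DeviationReport()
    rep.volume_recon = v_recon
    rep.volume_ref = v_ref
    rep.volume_diff = v_recon - v_ref
    rep.volume_diff_rel = (v_recon - v_ref) / v_ref * 100.0
    return rep


# -- pseudo-normal precomputation ------------------------------------------

def _angle_weighted_vertex_normals(mesh: trimesh.Trimesh) -> np.ndarray:
    faces = mesh.faces.view(np.ndarray)
    verts = mesh.vertices.view(np.ndarray)
    fn = mesh.face_normals.view(np.ndarray)
    out = np.zeros_like(verts)
    for c in range(3):
        vid = faces[:, c]
        e1 = verts[faces[:, (c + 1) % 3]] - verts[vid]
        e2 = verts[faces[:, (c + 2) % 3]] - verts[vid]
        cosang = np.einsum("ij,ij->i", e1, e2) / (
            np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1)
        )
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        np.add.at(out, vid, fn * ang[:, None])
    norms = np.linalg.norm(out, axis=1)
    return out / np.maximum(norms, 1e-30)[:, None]


def _edge_normals(mesh: trimesh.Trimesh) -> dict:
    fn = mesh.face_normals.view(np.ndarray)
    edges = mesh.edges_sorted.view(np.ndarray)      # (3 * n_faces, 2)
    face_of_edge = np.repeat(np.arange(len(mesh.faces)), 3)
    acc: dict[tuple, np.ndarray] = {}
    for (a, b), f in zip(map(tuple, edges), face_of_edge):
        key = (a, b)
        acc[key] = acc.get(key, 0.0) + fn[f]
    return acc


def _closest_point_triangles(points: np.ndarray, tri: np.ndarray):
    """Closest point on every triangle for every query point.

    Returns ``(closest (n, m, 3), bary_vw (n, m, 2))`` with the closest
    point expressed as ``a + v * ab + w * ac``.  Standard region-based
    point/triangle projection, fully vectorized.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    p = points[:, None, :]          # (n, 1, 3)
    ap = p - a
    d1 = np.einsum("mk,nmk->nm", ab, ap)
    d2 = np.einsum("mk,nmk->nm", ac, ap)
    bp = p - b
    d3 = np.einsum("mk,nmk->nm", ab, bp)
    d4 = np.einsum("mk,nmk->nm", ac, bp)
    cp_ = p - c
    d5 = np.einsum("mk,nmk->nm", ab, cp_)
    d6 = np.einsum("mk,nmk->nm", ac, cp_)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)                       # edge AB region
        w_ac = d2 / (d2 - d6)                       # edge AC region
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))  # edge BC region
        denom = va + vb + vc
        v_in = vb / denom
        w_in = vc / denom

    n, m = d1.shape
    v = np.empty((n, m))
    w = np.empty((n, m))
    # region conditions, applied in priority order (vertices, edges, face)
    cond_a = (d1 <= 0) & (d2 <= 0)
    cond_b = (d3 >= 0) & (d4 <= d3)
    cond_c = (d6 >= 0) & (d5 <= d6)
    cond_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    cond_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    cond_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)

    v[:] = np.nan_to_num(v_in)
    w[:] = np.nan_to_num(w_in)
    for cond, vv, ww in (
        (cond_bc, 1.0 - w_bc, w_bc),
        (cond_ac, 0.0, w_ac),
        (cond_ab, v_ab, 0.0),
        (cond_c, 0.0, 1.0),
        (cond_b, 1.0, 0.0),
        (cond_a, 0.0, 0.0),
    ):
        v = np.where(cond, np.nan_to_num(vv), v)
        w = np.where(cond, np.nan_to_num(ww), w)
    v = np.clip(v, 0.0, 1.0)
    w = np.clip(w, 0.0, 1.0)
    closest = a + v[..., None] * ab + w[..., None] * ac
    return closest, np.stack([v, w], axis=-1)
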