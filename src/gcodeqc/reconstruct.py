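"""Watertight solid reconstruction by layer-wise contour extrusion.

Within each layer, corrected (PC4) points are chained through their G-code
links; chains whose endpoints coincide within a closure tolerance become
closed 2D contours, nested even-odd into outer boundaries and holes.  Each
layer's contour set is extruded by the layer height into a prism slab, and
the slabs are merged with coincident interface faces cancelled, preserving
the characteristic step-wise side walls of layer-by-layer deposition.

Where a contour's points were retained as "single line" double candidates
(both offset candidates outside the infill, as happens for inner perimeters
on top and bottom layers), the outermost candidate represents the contour
and such rings never count as holes — only rings whose points were selected
by the infill test can bound a true cavity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
import trimesh
from shapely.geometry import Polygon
from shapely.geometry.polygon import orient

from .cloud import VERDICT_BOTH, StagedPointCloud
from .errors import GCodeQCError

_SNAP = 1e-6          # snap-rounding grid for traced chains, mm
_MIN_RING_PTS = 3


@dataclass
class LayerContourSet:
    """Closed contours (with even-odd nesting) of one layer."""

    layer_index: int
    z_bottom: float
    z_top: float
    contours: list = field(default_factory=list)      # shapely Polygons
    open_chains: list = field(default_factory=list)   # diagnostic polylines
    n_dropped_short: int = 0

    @property
    def net_area(self) -> float:
        return float(sum(p.area for p in self.contours))


def build_layer_contours(
    pc4: StagedPointCloud,
    layer: int,
    h: float,
    eps: float | None = None,
    w: float = 0.40,
    min_open_points: int = 8,
) -> LayerContourSet:
    """Trace closed contours of one layer from G-code chain order.

    ``eps`` is the endpoint-closure tolerance (default ``w / 4``); open
    chains are recorded as diagnostics, with very short ones only counted.
    """
    pc4.require_stage("PC4")
    if eps is None:
        eps = w / 4.0
    sel = pc4.layer == layer
    if not sel.any():
        raise GCodeQCError(f"layer {layer} has no points")
    superior = pc4.superior
    z_sel = pc4.points[sel, 2]
    if superior is not None:
        zn = z_sel + h * (~superior[sel])
    else:  # fall back: points sit either on z_n - h or z_n
        zn = np.full_like(z_sel, z_sel.max())
    vals, counts = np.unique(np.round(zn, 6), return_counts=True)
    z_top = float(vals[np.argmax(counts)])
    z_bottom = z_top - h

    cs = LayerContourSet(layer_index=layer, z_bottom=z_bottom, z_top=z_top)

    rings: list[tuple[np.ndarray, float]] = []   # (xy ring, single-line frac)
    for pid in np.unique(pc4.path_id[sel]):
        m = sel & (pc4.path_id == pid)
        xy, both_frac = _representatives(pc4, m)
        if len(xy) < 2:
            continue
        closed = np.linalg.norm(xy[0] - xy[-1]) <= eps
        if not closed or len(xy) < _MIN_RING_PTS + 1:
            if len(xy) < min_open_points:
                cs.n_dropped_short += 1
            else:
                cs.open_chains.append(xy)
            continue
        ring = np.round(xy / _SNAP) * _SNAP
        rings.append((ring, both_frac))

    cs.contours = _nest_even_odd(rings)
    return cs


def _representatives(pc4: StagedPointCloud, mask: np.ndarray):
    """One XY point per base G-code point: single-line doubles are collapsed
    to their outermost candidate (farther from the chain centroid)."""
    pts = pc4.points[mask, :2]
    verd = pc4.verdict[mask] if pc4.verdict is not None else None
    base = pc4.base_idx[mask] if pc4.base_idx is not None else None
    if verd is None or base is None or not (verd == VERDICT_BOTH).any():
        return pts, 0.0
    centroid = pts.mean(axis=0)
    keep = np.ones(len(pts), dtype=bool)
    i = 0
    n_both = 0
    while i < len(pts):
        if (
            verd[i] == VERDICT_BOTH
            and i + 1 < len(pts)
            and base[i + 1] == base[i]
        ):
            n_both += 1
            d0 = np.linalg.norm(pts[i] - centroid)
            d1 = np.linalg.norm(pts[i + 1] - centroid)
            keep[i + 1 if d0 >= d1 else i] = False
            i += 2
        else:
            i += 1
    frac = n_both / max(1, keep.sum())
    return pts[keep], frac


def _nest_even_odd(rings) -> list:
    """Even-odd nesting of closed rings into polygons with holes.

    Rings made predominantly of single-line double candidates may only act
    as outer boundaries; at odd depth they are discarded (they re-trace an
    inner perimeter, not a cavity).
    """
    polys = []
    for ring, frac in rings:
        try:
            p = Polygon(ring)
            if not p.is_valid:
                p = p.buffer(0)
        except Exception:  # noqa: BLE001 - degenerate ring
            continue
        if p.is_empty or p.area <= 0:
            continue
        if p.geom_type == "MultiPolygon":
            p = max(p.geoms, key=lambda g: g.area)
        polys.append((p, frac))
    if not polys:
        return []
    from shapely.geometry import Point

    depth = np.zeros(len(polys), dtype=int)
    for i, (pi, _) in enumerate(polys):
        probe = Point(pi.exterior.coords[0])   # a boundary point of ring i
        for j, (pj, _) in enumerate(polys):
            if i != j and pj.contains(probe):
                depth[i] += 1
    out = []
    order = sorted(range(len(polys)), key=lambda k: -polys[k][0].area)
    holes_of: dict[int, list] = {}
    for i in order:
        p, frac = polys[i]
        if depth[i] % 2 == 0:
            holes_of[i] = []
        else:
            if frac > 0.5:
                continue  # single-line inner ring, not a cavity
            # attach to the smallest even-depth ring containing it
            parents = [
                k for k in holes_of
                if polys[k][0].contains(p.representative_point())
            ]
            if parents:
                parent = min(parents, key=lambda k: polys[k][0].area)
                holes_of[parent].append(p.exterior.coords)
    return [
        orient(Polygon(polys[i][0].exterior.coords, holes_of[i]))
        for i in sorted(holes_of)
    ]


def extrude_layer(cs: LayerContourSet) -> trimesh.Trimesh:
    """Extrude a contour set into a watertight prism slab.

    Caps are constrained-Delaunay triangulations of the polygons (bottom at
    ``z_bottom`` facing down, top at ``z_top`` facing up); side walls follow
    the exterior and hole rings.  Slab volume equals net polygon area times
    layer height.
    """
    polys = [p for p in cs.contours if p.area > 1e-12]
    if not polys:
        raise GCodeQCError(
            f"layer {cs.layer_index}: no closed contours to extrude"
        )
    meshes = [_extrude_polygon(p, cs.z_bottom, cs.z_top) for p in polys]
    mesh = trimesh.util.concatenate(meshes) if len(meshes) > 1 else meshes[0]
    return mesh


def _extrude_polygon(poly: Polygon, z0: float, z1: float) -> trimesh.Trimesh:
    poly = orient(poly)   # exterior CCW, holes CW
    tris = shapely.constrained_delaunay_triangles(poly)
    cap = []
    for t in tris.geoms:
        xy = np.asarray(t.exterior.coords)[:3]
        # enforce CCW so the top cap faces +Z
        u, v = xy[1] - xy[0], xy[2] - xy[0]
        if u[0] * v[1] - u[1] * v[0] < 0:
            xy = xy[::-1]
        cap.append(xy)
    cap = np.asarray(cap)                      # (k, 3, 2)

    verts: list[np.ndarray] = []
    faces: list[list[int]] = []

    def add_tri(p0, p1, p2):
        i = len(verts)
        verts.extend([p0, p1, p2])
        faces.append([i, i + 1, i + 2])

    for t in cap:
        a, b, c = (np.append(p, z1) for p in t)
        add_tri(a, b, c)                       # top cap, +Z
        a, b, c = (np.append(p, z0) for p in t)
        add_tri(a, c, b)                       # bottom cap, -Z
    for ring in [poly.exterior, *poly.interiors]:
        xy = np.asarray(ring.coords)
        for k in range(len(xy) - 1):
            a0 = np.append(xy[k], z0)
            b0 = np.append(xy[k + 1], z0)
            a1 = np.append(xy[k], z1)
            b1 = np.append(xy[k + 1], z1)
            add_tri(a0, b0, b1)
            add_tri(a0, b1, a1)

    mesh = trimesh.Trimesh(vertices=np.asarray(verts), faces=np.asarray(faces),
                           process=True)
    mesh.update_faces(mesh.nondegenerate_faces())
    return mesh


def merge_layers(slabs: list[trimesh.Trimesh]) -> trimesh.Trimesh:
    """Merge Z-disjoint slabs into one mesh, cancelling coincident opposing
    faces at slab interfaces.

    Because the slabs occupy disjoint ``[k*h, (k+1)*h)`` bands, their union
    volume is exactly the sum of slab volumes; interface faces that appear
    identically (on a shared snapped vertex grid) in the top cap of one slab
    and the bottom cap of the next cancel pairwise, leaving exposed tread
    faces intact.
    """
    if not slabs:
        raise GCodeQCError("no slabs to merge")
    if len(slabs) == 1:
        return slabs[0]
    bounds = sorted((m.bounds[0][2], m.bounds[1][2]) for m in slabs)
    for (lo0, hi0), (lo1, _hi1) in zip(bounds, bounds[1:]):
        if lo1 < hi0 - 1e-9:
            raise GCodeQCError(
                f"slabs overlap in Z ({hi0:.4f} > {lo1:.4f}); layers must be disjoint"
            )
    big = trimesh.util.concatenate(slabs)
    v = np.round(big.vertices / _SNAP) * _SNAP
    f = big.faces

    tri_v = v[f].round(6)                                 # (k, 3, 3)
    # canonical key: vertex rows in lexicographic order (orientation-free)
    order = np.lexsort((tri_v[..., 2], tri_v[..., 1], tri_v[..., 0]), axis=1)
    keys = np.take_along_axis(tri_v, order[..., None], axis=1).reshape(len(f), 9)
    _, inverse, counts = np.unique(
        keys, axis=0, return_inverse=True, return_counts=True
    )
    keep = counts[inverse] == 1   # faces appearing twice (opposing caps) cancel
    mesh = trimesh.Trimesh(vertices=v, faces=f[keep], process=True)
    mesh.update_faces(mesh.nondegenerate_faces())
    return mesh


def reconstruct_solid(
    pc4: StagedPointCloud,
    h: float,
    w: float = 0.40,
    eps: float | None = None,
) -> tuple[trimesh.Trimesh, list[LayerContourSet]]:
    """Full layer-extrusion reconstruction of a corrected cloud.

    Layers without any closed contour are skipped and reported in the
    returned contour sets (empty ``contours``).
    """
    sets = []
    for layer in np.unique(pc4.layer):
        cs = build_layer_contours(pc4, int(layer), h, eps=eps, w=w)
        sets.append(cs)
    # a final layer shifted to the true top height (partial-layer handling)
    # may overlap the slab below; clip its bottom so the union is exact
    sets.sort(key=lambda cs: cs.z_bottom)
    for prev, cs in zip(sets, sets[1:]):
        if cs.z_bottom < prev.z_top - 1e-9:
            cs.z_bottom = prev.z_top
    slabs = [extrude_layer(cs) for cs in sets if cs.contours]
    if not slabs:
        raise GCodeQCError("no layer produced a closed contour")
    return merge_layers(slabs), sets
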