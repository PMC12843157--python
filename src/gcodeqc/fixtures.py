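"""Synthetic ground-truth scenes: analytic solids, the step calibration
object, and a deterministic mini-slicer.

The mini-slicer emulates the toolpath structure of desktop FDM slicers for
simple watertight solids — two inset perimeters plus 100% rectilinear infill
alternating 0/90 degrees per layer, absolute-E linear moves, header comments
carrying the process parameters — without reproducing any commercial
slicer's exact behaviour.  It is bit-deterministic: the same scene always
yields byte-identical G-code, which makes it the reference against which
repeatability of the analysis pipeline itself can be checked.

Process defaults match the study conditions used throughout the package:
layer height 0.20 mm, line width 0.40 mm, two perimeters, 100% rectilinear
infill.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import trimesh
from shapely.geometry import LineString, Polygon
from shapely.geometry.polygon import orient

from .errors import GCodeQCError
from .transform import RigidTransform

CO_DIMS = (10.00, 6.25, 8.75)
_FILAMENT_AREA = math.pi * (1.75 / 2.0) ** 2   # nominal 1.75 mm filament


@dataclass
class SlicingParams:
    layer_height: float = 0.20
    line_width: float = 0.40
    n_perimeters: int = 2
    infill: str = "rectilinear"
    infill_density: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layer_height <= 0 or self.line_width <= 0:
            raise ValueError("process parameters must be positive")


@dataclass
class FixtureScene:
    """A model plus the step calibration object, with a ground-truth rigid
    placement emulating the slicer's unknown coordinate system.

    ``model_mesh`` and ``co_mesh`` are in the *reference* frame (calibration
    object near the global origin, model beside it); the placement is
    applied only when slicing.
    """

    model_mesh: trimesh.Trimesh
    co_mesh: trimesh.Trimesh
    placement: RigidTransform = field(default_factory=RigidTransform.identity)
    params: SlicingParams = field(default_factory=SlicingParams)


def _prism(profile_xy: list[tuple[float, float]], length: float,
           axis_order=(0, 1, 2)) -> trimesh.Trimesh:
    """Right prism over a simple polygon, optionally with permuted axes."""
    poly = orient(Polygon(profile_xy))
    import shapely

    tris = shapely.constrained_delaunay_triangles(poly)
    verts, faces = [], []

    def add(p0, p1, p2):
        i = len(verts)
        verts.extend([p0, p1, p2])
        faces.append([i, i + 1, i + 2])

    for t in tris.geoms:
        xy = np.asarray(t.exterior.coords)[:3]
        u, v = xy[1] - xy[0], xy[2] - xy[0]
        if u[0] * v[1] - u[1] * v[0] < 0:
            xy = xy[::-1]
        a, b, c = (np.append(p, length) for p in xy)
        add(a, b, c)
        a, b, c = (np.append(p, 0.0) for p in xy)
        add(a, c, b)
    ring = np.asarray(poly.exterior.coords)
    for k in range(len(ring) - 1):
        a0 = np.append(ring[k], 0.0)
        b0 = np.append(ring[k + 1], 0.0)
        a1 = np.append(ring[k], length)
        b1 = np.append(ring[k + 1], length)
        add(a0, b0, b1)
        add(a0, b1, a1)
    v = np.asarray(verts)[:, axis_order]
    mesh = trimesh.Trimesh(vertices=v, faces=np.asarray(faces), process=True)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def make_calibration_object() -> trimesh.Trimesh:
    """The step-shaped calibration fiducial: two orthogonal rectangular
    blocks, overall bounding box exactly 10.00 x 6.25 x 8.75 mm (X, Y, Z),
    min corner at the origin.

    The step profile lies in the Y-Z plane and is extruded along X; the
    shape has three mutually perpendicular reference faces on the coordinate
    planes and no rotational symmetry, which pins the ICP orientation.
    """
    x, y, z = CO_DIMS
    z_step = 4.4   # shelf on the 0.2 mm layer lattice (sliceable step height)
    profile_yz = [
        (0.0, 0.0), (y, 0.0), (y, z_step),
        (y / 2.0, z_step), (y / 2.0, z), (0.0, z),
    ]
    # prism built in (y, z, s) with s along X; reorder to (s, y, z)
    return _prism(profile_yz, x, axis_order=(2, 0, 1))


def make_box(extents=(20.0, 20.0, 2.0)) -> trimesh.Trimesh:
    """Axis-aligned box with min corner at the origin."""
    ex, ey, ez = extents
    return _prism([(0, 0), (ex, 0), (ex, ey), (0, ey)], ez)


def make_lbeam(size: float = 20.0, cut: float = 10.0, height: float = 5.0) -> trimesh.Trimesh:
    """L-shaped prism: a ``size`` square with a ``cut`` square removed from
    the +X/+Y corner."""
    s, c = size, cut
    return _prism([(0, 0), (s, 0), (s, s - c), (s - c, s - c), (s - c, s), (0, s)], height)


def make_ngon_cylinder(radius: float = 8.0, n: int = 64, height: float = 4.0) -> trimesh.Trimesh:
    """Regular n-gon prism approximating a cylinder, centered on the Z axis."""
    ang = 2.0 * np.pi * np.arange(n) / n
    pts = [(radius * math.cos(a), radius * math.sin(a)) for a in ang]
    return _prism(pts, height)


def compose_scene(
    model: trimesh.Trimesh,
    placement: RigidTransform | None = None,
    seed: int = 0,
    gap: float = 5.0,
    params: SlicingParams | None = None,
) -> FixtureScene:
    """Place the calibration object near the origin and the model beside it.

    ``placement`` is the ground-truth rigid motion the slicer applies to the
    whole scene (recorded for recovery tests); the composed reference frame
    itself is deterministic.  Models closer than 2 mm to the calibration
    object are rejected.
    """
    if placement is None:
        placement = RigidTransform.identity()
    co = make_calibration_object()
    model = model.copy()
    shift = np.array([CO_DIMS[0] + gap, 0.0, 0.0]) - model.bounds[0]
    model.apply_translation(shift)
    clearance = model.bounds[0][0] - co.bounds[1][0]
    if clearance < 2.0:
        raise GCodeQCError(
            f"model too close to the calibration object ({clearance:.2f} mm < 2 mm)"
        )
    p = params or SlicingParams(seed=seed)
    return FixtureScene(model_mesh=model, co_mesh=co, placement=placement, params=p)


# -- mini-slicer ------------------------------------------------------------

def mini_slice(scene: FixtureScene) -> str:
    """Deterministic G-code for a fixture scene (perimeters + rectilinear
    infill, absolute E, header comments carrying the process parameters).

    Layers are cut at mid-layer planes ``z0 + (k - 1/2) h`` and printed with
    the nozzle at ``z0 + k h``.  When the layer height does not divide the
    scene height and the remainder exceeds ``h / 4``, a final layer is
    printed with the nozzle shifted to the true top height (the way most
    slicers close the top surface); smaller remainders are omitted.
    """
    p = scene.params
    h, w = p.layer_height, p.line_width
    placed = []
    for mesh in (scene.model_mesh, scene.co_mesh):
        if not mesh.is_watertight:
            raise GCodeQCError("mini-slicer requires watertight input meshes")
        m = mesh.copy()
        m.apply_transform(scene.placement.to_matrix())
        placed.append(m)

    z0 = min(m.bounds[0][2] for m in placed)
    z_top = max(m.bounds[1][2] for m in placed)
    n_layers = int(math.floor((z_top - z0) / h + 1e-9))

    lines: list[str] = [
        "; gcodeqc mini-slicer",
        f"; layer_height = {h:.2f}",
        f"; line_width = {w:.2f}",
        "; extrusion_multiplier = 1.00",
        f"; seed = {p.seed}",
        "G21", "G90", "M82", "G92 E0",
    ]
    e = 0.0
    e_per_mm = w * h / _FILAMENT_AREA
    pos: np.ndarray | None = None

    def travel(pt) -> None:
        nonlocal pos
        lines.append(f"G0 X{pt[0]:.3f} Y{pt[1]:.3f} F7800")
        pos = np.asarray(pt, dtype=float)

    def extrude_polyline(coords) -> None:
        nonlocal e, pos
        coords = [np.round(np.asarray(c, dtype=float), 3) for c in coords]
        travel(coords[0])
        for a, b in zip(coords, coords[1:]):
            seg = float(np.linalg.norm(b - a))
            if seg <= 1e-9:
                continue
            e += seg * e_per_mm
            lines.append(f"G1 X{b[0]:.3f} Y{b[1]:.3f} E{e:.5f} F4800")
            pos = b

    remainder = (z_top - z0) - n_layers * h
    levels = [(z0 + (k - 0.5) * h, z0 + k * h) for k in range(1, n_layers + 1)]
    if remainder > h / 4.0:
        levels.append((z_top - 0.5 * h, z_top))

    for k, (zc, zn) in enumerate(levels, start=1):
        lines.append(f"; layer {k - 1}")
        lines.append(f"G0 Z{zn:.3f} F7800")
        polys = []
        for m in placed:
            polys.extend(_cross_section(m, zc))
        for poly in polys:
            for ring in _perimeter_rings(poly, w, p.n_perimeters):
                extrude_polyline(_seamed(ring))
            for seg in _infill_segments(poly, w, angle_deg=90.0 * ((k - 1) % 2)):
                extrude_polyline(seg)
    return "\n".join(lines) + "\n"


def _cross_section(mesh: trimesh.Trimesh, z: float) -> list[Polygon]:
    section = mesh.section(plane_origin=[0.0, 0.0, z], plane_normal=[0, 0, 1])
    if section is None:
        return []
    to_2d = np.eye(4)
    to_2d[2, 3] = -z
    path2d, _ = section.to_2D(to_2D=to_2d)
    return [orient(pg) for pg in path2d.polygons_full]


def _perimeter_rings(poly: Polygon, w: float, n_perimeters: int):
    """Centerline rings of the inset perimeters (outermost first)."""
    for i in range(n_perimeters):
        inset = poly.buffer(-(0.5 + i) * w, join_style=2, mitre_limit=2.0)
        if inset.is_empty:
            return
        geoms = inset.geoms if inset.geom_type == "MultiPolygon" else [inset]
        for g in geoms:
            yield np.asarray(g.exterior.coords)
            for hole in g.interiors:
                yield np.asarray(hole.coords)


def _infill_segments(poly: Polygon, w: float, angle_deg: float):
    """Rectilinear hatch segments at spacing ``w`` over the region inside
    both perimeters, on a fixed global lattice (deterministic)."""
    region = poly.buffer(-2.0 * w, join_style=2, mitre_limit=2.0)
    if region.is_empty:
        return
    minx, miny, maxx, maxy = region.bounds
    horizontal = abs(angle_deg) < 45.0
    lo, hi = (miny, maxy) if horizontal else (minx, maxx)
    k0 = math.ceil((lo - 0.5 * w) / w)
    k1 = math.floor((hi - 0.5 * w) / w)
    flip = False
    for k in range(k0, k1 + 1):
        c = (k + 0.5) * w
        if horizontal:
            line = LineString([(minx - 1.0, c), (maxx + 1.0, c)])
        else:
            line = LineString([(c, miny - 1.0), (c, maxy + 1.0)])
        inter = region.intersection(line)
        if inter.is_empty:
            continue
        geoms = inter.geoms if hasattr(inter, "geoms") else [inter]
        for g in geoms:
            if g.geom_type != "LineString" or g.length < 1e-6:
                continue
            coords = np.asarray(g.coords)
            yield coords[::-1] if flip else coords
            flip = not flip


def _seamed(ring: np.ndarray) -> np.ndarray:
    """Rotate a closed ring to start at its lexicographically smallest
    vertex (deterministic seam placement), keeping it closed."""
    pts = np.asarray(ring)[:-1]   # drop duplicate closing vertex
    i = np.lexsort((pts[:, 1], pts[:, 0]))[0]
    rolled = np.roll(pts, -i, axis=0)
    return np.vstack([rolled, rolled[:1]])


def total_path_length(gcode: str) -> float:
    """Total extruding path length implied by the emitted E values (mm of
    XY travel, bookkeeping helper for conservation checks)."""
    from .gcode import parse_gcode

    tp = parse_gcode(gcode)
    return float(tp.segment_lengths().sum())
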