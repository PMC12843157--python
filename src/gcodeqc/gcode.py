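"""G-code parsing and nozzle-centerline point extraction.

Supports the RepRap-style linear-move dialect emitted by desktop FDM slicers:
``G0``/``G1`` moves with ``X Y Z E F`` words, ``G90``/``G91`` positioning
modes, ``M82``/``M83`` extruder modes and ``G92`` register resets.  Arc moves
(``G2``/``G3``) and inch mode (``G20``) are rejected rather than approximated.

An extrusion *segment* is a directed planar move ``(x1, y1, z1) -> (x2, y2,
z2)`` during which fresh filament is deposited.  Retraction (E decreasing)
and the subsequent un-retract are treated as travels: deposition resumes only
once the cumulative extruded length exceeds its pre-retraction maximum, which
prevents phantom segments immediately after a retract.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cloud import StagedPointCloud
from .errors import DialectError, EmptyCloudError, MalformedSegmentError, UnitError

_WORD_RE = re.compile(r"([A-Za-z])\s*([-+]?[0-9]*\.?[0-9]+)")

# Header-comment patterns used by common slicers to record process settings.
_META_PATTERNS = {
    "layer_height": re.compile(r"layer[ _]?height\s*[:=]\s*([0-9]*\.?[0-9]+)", re.I),
    "line_width": re.compile(
        r"(?:line|extrusion)[ _]?width\s*[:=]\s*([0-9]*\.?[0-9]+)", re.I
    ),
    "extrusion_multiplier": re.compile(
        r"extrusion[ _]?multiplier\s*[:=]\s*([0-9]*\.?[0-9]+)", re.I
    ),
}

_VERTEX_TOL = 1e-9       # segment chaining tolerance, mm
_LOOP_TOL = 1e-6         # closed-contour detection tolerance, mm


@dataclass(frozen=True)
class GCodeCommand:
    """One recognized G-code line (unrecognized opcodes are tagged ignored)."""

    code: str
    x: float | None = None
    y: float | None = None
    z: float | None = None
    e: float | None = None
    f: float | None = None
    ignored: bool = False


@dataclass
class ProcessMeta:
    """Process parameters attached to a toolpath.

    ``source`` records where each value came from: a slicer header comment,
    modal analysis of the Z steps between extrusion layers, or the user
    defaults (with a warning).
    """

    layer_height: float
    line_width: float
    extrusion_multiplier: float = 1.0
    source: dict = field(default_factory=dict)
    dialect: str = "reprap-linear"

    def __post_init__(self) -> None:
        if self.layer_height <= 0:
            raise ValueError("layer height must be positive")
        if self.line_width <= 0:
            raise ValueError("line width must be positive")


@dataclass
class Toolpath:
    """Ordered extrusion segments plus travel moves and process metadata.

    Segments are stored columnar for vectorized downstream processing:
    ``start``/``end`` are ``(n, 3)`` arrays, ``delta_e`` the deposited
    filament length per segment, ``layer`` the layer index (rank of the
    segment Z among distinct ascending extrusion heights) and ``path_id``
    groups contiguous chains of segments not interrupted by travels.
    """

    start: np.ndarray
    end: np.ndarray
    delta_e: np.ndarray
    layer: np.ndarray
    path_id: np.ndarray
    travels: np.ndarray          # (m, 6) travel moves: x1 y1 z1 x2 y2 z2
    meta: ProcessMeta

    @property
    def n_segments(self) -> int:
        return len(self.delta_e)

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.end - self.start, axis=1)


def tokenize_line(line: str) -> GCodeCommand | None:
    """Parse one raw line into a command, or ``None`` for blank/comment lines."""
    code_part = line.split(";", 1)[0].strip()
    if not code_part:
        return None
    words = _WORD_RE.findall(code_part)
    if not words:
        return None
    letter, number = words[0]
    code = f"{letter.upper()}{number.rstrip('.')}" if letter.upper() in "GMT" else None
    if code is None:
        return None
    params: dict[str, float] = {}
    for letter, number in words[1:]:
        key = letter.lower()
        if key in ("x", "y", "z", "e", "f"):
            val = float(number)
            if not math.isfinite(val):
                raise MalformedSegmentError(f"non-finite coordinate in {line!r}")
            params[key] = val
    known = {"G0", "G1", "G2", "G3", "G20", "G21", "G90", "G91", "G92",
             "M82", "M83"}
    return GCodeCommand(code=code, ignored=code not in known, **params)


def parse_gcode(text: str, defaults: ProcessMeta | None = None) -> Toolpath:
    """Parse G-code source into a normalized :class:`Toolpath`.

    ``defaults`` supplies the layer height / line width used when neither the
    header comments nor modal Z analysis can determine them.
    """
    pos = np.zeros(3)
    has_pos = np.zeros(3, dtype=bool)   # axis seen at least once
    absolute_xyz = True
    absolute_e = True
    e_reg = 0.0      # the E register (what G92 resets)
    e_cum = 0.0      # physical cumulative filament (sum of deltas)
    e_max = 0.0      # high-water mark; deposition requires e_cum to exceed it

    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []
    deltas: list[float] = []
    travels: list[list[float]] = []
    seg_after_travel: list[bool] = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        cmd = tokenize_line(raw)
        if cmd is None or cmd.ignored:
            continue
        code = cmd.code
        if code in ("G2", "G3"):
            raise DialectError(
                f"line {lineno}: arc move {code} unsupported (linear dialect only)"
            )
        if code == "G20":
            raise UnitError(f"line {lineno}: inch mode (G20) unsupported, mm only")
        if code == "G21":
            continue
        if code == "G90":
            absolute_xyz = True
            absolute_e = True
            continue
        if code == "G91":
            absolute_xyz = False
            absolute_e = False
            continue
        if code == "M82":
            absolute_e = True
            continue
        if code == "M83":
            absolute_e = False
            continue
        if code == "G92":
            for axis, i in (("x", 0), ("y", 1), ("z", 2)):
                v = getattr(cmd, axis)
                if v is not None:
                    pos[i] = v
                    has_pos[i] = True
            if cmd.e is not None:
                e_reg = cmd.e
            continue
        # G0 / G1 linear move
        new_pos = pos.copy()
        for axis, i in (("x", 0), ("y", 1), ("z", 2)):
            v = getattr(cmd, axis)
            if v is not None:
                new_pos[i] = v if absolute_xyz else pos[i] + v
                has_pos[i] = True
        de = 0.0
        if cmd.e is not None:
            de = (cmd.e - e_reg) if absolute_e else cmd.e
            e_reg = cmd.e if absolute_e else e_reg + cmd.e
        new_cum = e_cum + de
        deposited = new_cum - max(e_cum, e_max)   # fresh filament this move
        moved = not np.array_equal(new_pos, pos)
        has_motion_words = any(
            getattr(cmd, axis) is not None for axis in ("x", "y", "z")
        )
        # a command naming coordinates equal to the current position is a
        # degenerate (zero-length) segment; a bare in-place prime is not
        if deposited > 0.0 and (moved or has_motion_words):
            if abs(new_pos[2] - pos[2]) > _VERTEX_TOL:
                raise MalformedSegmentError(
                    f"line {lineno}: extruding move changes Z "
                    f"({pos[2]:.4f} -> {new_pos[2]:.4f}); non-planar deposition"
                )
            starts.append(pos.copy())
            ends.append(new_pos.copy())
            deltas.append(deposited)
            seg_after_travel.append(False)
        elif moved:
            travels.append([*pos, *new_pos])
            if seg_after_travel:
                # the next segment (if any) starts a new path
                seg_after_travel[-1] = True
        e_cum = new_cum
        e_max = max(e_max, new_cum)
        pos = new_pos

    start = np.asarray(starts, dtype=float).reshape(-1, 3)
    end = np.asarray(ends, dtype=float).reshape(-1, 3)
    delta_e = np.asarray(deltas, dtype=float)
    n = len(delta_e)

    # Path ids: a new path begins when the chain of vertices breaks, either
    # because a travel intervened or because the coordinates simply jump.
    path_id = np.zeros(n, dtype=np.int64)
    pid = 0
    for i in range(1, n):
        broken = seg_after_travel[i - 1] or not np.allclose(
            end[i - 1], start[i], atol=_VERTEX_TOL
        )
        if broken:
            pid += 1
        path_id[i] = pid

    # Layer index: rank of the segment Z among distinct ascending extrusion Z.
    if n:
        zs = start[:, 2]
        uniq = np.unique(zs)
        layer = np.searchsorted(uniq, zs).astype(np.int64)
    else:
        layer = np.zeros(0, dtype=np.int64)

    meta = _resolve_meta(text, start[:, 2] if n else np.zeros(0), defaults)
    return Toolpath(
        start=start, end=end, delta_e=delta_e, layer=layer, path_id=path_id,
        travels=np.asarray(travels, dtype=float).reshape(-1, 6), meta=meta,
    )


def _resolve_meta(
    text: str, extrusion_z: np.ndarray, defaults: ProcessMeta | None
) -> ProcessMeta:
    """Header comments, then modal Z-step analysis, then user defaults."""
    values: dict[str, float] = {}
    source: dict[str, str] = {}
    header = "\n".join(
        ln for ln in text.splitlines() if ln.lstrip().startswith(";")
    )
    for key, pat in _META_PATTERNS.items():
        m = pat.search(header)
        if m:
            values[key] = float(m.group(1))
            source[key] = "header"
    if "layer_height" not in values:
        uniq = np.unique(extrusion_z)
        steps = np.diff(uniq)
        steps = steps[steps > 1e-6]
        if len(steps):
            vals, counts = np.unique(np.round(steps, 6), return_counts=True)
            values["layer_height"] = float(vals[np.argmax(counts)])
            source["layer_height"] = "modal"
    for key in ("layer_height", "line_width"):
        if key not in values:
            if defaults is None:
                raise ValueError(
                    f"{key} not recoverable from G-code and no defaults given"
                )
            values[key] = getattr(defaults, key)
            source[key] = "default"
            warnings.warn(
                f"{key} not found in G-code header; using default "
                f"{values[key]:.3f} mm",
                stacklevel=2,
            )
    if "extrusion_multiplier" not in values:
        values["extrusion_multiplier"] = (
            defaults.extrusion_multiplier if defaults is not None else 1.0
        )
        source["extrusion_multiplier"] = "default"
    return ProcessMeta(
        layer_height=values["layer_height"],
        line_width=values["line_width"],
        extrusion_multiplier=values["extrusion_multiplier"],
        source=source,
    )


def extract_centerline_points(tp: Toolpath, spacing: float = 0.05) -> StagedPointCloud:
    """Sample the raw nozzle-centerline cloud (stage ``PC1``).

    Every segment contributes its two endpoints plus intermediate samples at
    most ``spacing`` apart, so rasterization at a voxel size of
    ``2 * spacing`` cannot skip voxels.  Tangents are taken from the original
    G-code path vertices (central difference at segment junctions, one-sided
    at open path ends, wrap-around on closed loops), not from the resampled
    points.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if tp.n_segments == 0:
        raise EmptyCloudError("toolpath has no extrusion segments")

    vec = tp.end - tp.start
    lengths = np.linalg.norm(vec, axis=1)
    seg_dir = np.divide(
        vec, lengths[:, None], out=np.zeros_like(vec), where=lengths[:, None] > 0
    )
    junction_tangent = _junction_tangents(tp, seg_dir)

    pts, layers, paths, tangents = [], [], [], []
    for i in range(tp.n_segments):
        L = lengths[i]
        if L == 0.0:
            t = np.zeros((1,))
        else:
            ndiv = max(1, int(np.ceil(L / spacing)))
            t = np.linspace(0.0, 1.0, ndiv + 1)
        p = tp.start[i] + t[:, None] * vec[i]
        tang = np.tile(seg_dir[i], (len(t), 1))
        # endpoint tangents come from the neighbouring G-code vertices
        tang[0] = junction_tangent[i, 0]
        tang[-1] = junction_tangent[i, 1]
        pts.append(p)
        layers.append(np.full(len(t), tp.layer[i], dtype=np.int64))
        paths.append(np.full(len(t), tp.path_id[i], dtype=np.int64))
        tangents.append(tang)

    points = np.concatenate(pts)
    layer = np.concatenate(layers)
    path = np.concatenate(paths)
    tangent = np.concatenate(tangents)
    from .cloud import _chain_links

    prev, nxt = _chain_links(path)
    return StagedPointCloud(points, prev, nxt, layer, path, tangent, stage="PC1")


def _junction_tangents(tp: Toolpath, seg_dir: np.ndarray) -> np.ndarray:
    """Per-segment (start, end) tangents from neighbouring G-code vertices.

    Junction tangents are the central difference between the previous and the
    following path vertex; open path ends fall back to the segment direction;
    paths whose first and last vertices coincide (closed contours) wrap.
    """
    n = tp.n_segments
    out = np.empty((n, 2, 3))
    out[:, 0] = seg_dir
    out[:, 1] = seg_dir
    for pid in np.unique(tp.path_id):
        idx = np.flatnonzero(tp.path_id == pid)
        verts = np.vstack([tp.start[idx], tp.end[idx[-1]][None]])
        closed = len(idx) > 1 and np.allclose(verts[0], verts[-1], atol=_LOOP_TOL)
        nv = len(verts)
        for j in range(nv):
            if 0 < j < nv - 1:
                d = verts[j + 1] - verts[j - 1]
            elif closed:
                d = verts[(j + 1) % (nv - 1)] - verts[j - 1 if j else nv - 2]
            else:
                continue  # open end: keep one-sided segment direction
            norm = np.linalg.norm(d)
            if norm < _VERTEX_TOL:
                continue
            d = d / norm
            if j < nv - 1:
                out[idx[j], 0] = d
            if j > 0:
                out[idx[j - 1], 1] = d
    return out


def total_extruded(tp: Toolpath) -> float:
    """Sum of per-segment deposited filament lengths (mm)."""
    return float(tp.delta_e.sum())
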