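"""STL and point-cloud file I/O (mm units throughout)."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import trimesh

from .cloud import StagedPointCloud
from .errors import GCodeQCError


def read_stl(path: str | Path) -> trimesh.Trimesh:
    """Load a binary or ASCII STL as a :class:`trimesh.Trimesh`.

    A non-watertight mesh is returned with a warning; volume operations
    downstream will refuse it.
    """
    path = Path(path)
    try:
        mesh = trimesh.load_mesh(path, file_type="stl", process=True)
    except Exception as exc:  # noqa: BLE001 - normalize loader errors
        raise GCodeQCError(f"cannot parse STL {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise GCodeQCError(f"{path} contains no triangles")
    if not mesh.is_watertight:
        warnings.warn(f"{path} is not watertight; volume metrics will refuse it",
                      stacklevel=2)
    return mesh


def write_stl(mesh: trimesh.Trimesh, path: str | Path, ascii: bool = False) -> None:
    path = Path(path)
    data = trimesh.exchange.stl.export_stl_ascii(mesh).encode() if ascii \
        else trimesh.exchange.stl.export_stl(mesh)
    path.write_bytes(data)


def write_pointcloud(pc: StagedPointCloud, path: str | Path) -> None:
    """Write a staged cloud as ASCII PLY (with stage/verdict attributes) or XYZ."""
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        np.savetxt(path, pc.points, fmt="%.6f")
        return
    verdict = pc.verdict if pc.verdict is not None else np.zeros(len(pc), np.int64)
    lines = [
        "ply", "format ascii 1.0",
        f"comment stage={pc.stage} role={pc.role}",
        f"element vertex {len(pc)}",
        "property float x", "property float y", "property float z",
        "property int layer", "property int verdict",
        "end_header",
    ]
    body = [
        f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {l} {v}"
        for p, l, v in zip(pc.points, pc.layer, verdict)
    ]
    path.write_text("\n".join(lines + body) + "\n")
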