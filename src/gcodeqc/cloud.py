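"""Staged point clouds tracking the correction pipeline.

The reconstruction pipeline refines the raw nozzle-centerline cloud through
four stages:

* ``PC1`` — points sampled along extruding moves (nozzle centerline),
* ``PC2`` — shell-filtered (infill / inner-perimeter points removed),
* ``PC3`` — XY offset applied (nozzle radius, infill decision logic),
* ``PC4`` — Z deposition-plane correction applied.

A cloud also carries a *role*: ``UNSPLIT`` before the calibration split,
``CALIBRATION`` / ``MODEL`` afterwards, and ``TPCM`` once the registration
transform has been applied to the model subset.

Points keep ``prev``/``next`` links following G-code order (broken at travel
moves) plus the tangent direction derived from the neighbouring G-code path
vertices, which the XY correction needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import EmptyCloudError, StageError

STAGES = ("PC1", "PC2", "PC3", "PC4")
ROLES = ("UNSPLIT", "MODEL", "CALIBRATION", "TPCM")

# XY-correction verdicts (per corrected point, recorded for provenance/QC).
VERDICT_NONE = 0        # no XY correction applied yet
VERDICT_KEEP_PRIME = 1  # one candidate in infill, the P' side kept
VERDICT_KEEP_DOUBLE = 2  # the P'' side kept
VERDICT_BOTH = 3        # neither candidate in infill: "single line", both kept
VERDICT_ERROR = 4       # both candidates in infill: point dropped


@dataclass
class StagedPointCloud:
    points: np.ndarray                 # (n, 3) float64, mm
    prev: np.ndarray                   # (n,) int64 index into this cloud, -1 = none
    next: np.ndarray                   # (n,) int64 index, -1 = none
    layer: np.ndarray                  # (n,) int64 layer index
    path_id: np.ndarray                # (n,) int64 contiguous-extrusion path id
    tangent: np.ndarray                # (n, 3) unit tangent from G-code neighbours
    stage: str = "PC1"
    role: str = "UNSPLIT"
    base_idx: np.ndarray | None = None   # provenance into the previous stage
    verdict: np.ndarray | None = None    # XY verdict per point (PC3 and later)
    superior: np.ndarray | None = None   # Z-correction superior-edge flag (PC4)
    stats: dict = field(default_factory=dict)  # per-stage diagnostic counts

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        n = len(self.points)
        for name in ("prev", "next", "layer", "path_id"):
            arr = np.asarray(getattr(self, name), dtype=np.int64).reshape(-1)
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != point count {n}")
            setattr(self, name, arr)
        self.tangent = np.asarray(self.tangent, dtype=float).reshape(-1, 3)
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")

    def __len__(self) -> int:
        return len(self.points)

    def require_stage(self, stage: str) -> None:
        if self.stage != stage:
            raise StageError(
                f"operation expects a {stage} cloud, got {self.stage}; "
                "stages advance strictly PC1 -> PC2 -> PC3 -> PC4"
            )

    def select(self, mask: np.ndarray, stage: str | None = None) -> "StagedPointCloud":
        """Subset by boolean ``mask``, re-threading links across removed points.

        Links only bridge removals *within* the same contiguous path; path
        breaks introduced by travel moves are preserved.
        """
        mask = np.asarray(mask, dtype=bool)
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise EmptyCloudError("selection removed every point")
        pts = self.points[idx]
        layer = self.layer[idx]
        path = self.path_id[idx]
        tang = self.tangent[idx]
        prev, nxt = _chain_links(path)
        base = idx if self.base_idx is None else self.base_idx[idx]
        verdict = None if self.verdict is None else self.verdict[idx]
        superior = None if self.superior is None else self.superior[idx]
        return StagedPointCloud(
            pts, prev, nxt, layer, path, tang,
            stage=stage or self.stage, role=self.role,
            base_idx=base, verdict=verdict, superior=superior,
        )

    def with_role(self, role: str) -> "StagedPointCloud":
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return replace(self, role=role)

    def links_mutual(self) -> bool:
        """Check the link invariant next(prev(i)) == i where both exist."""
        ok = True
        for i in range(len(self)):
            p = self.prev[i]
            if p >= 0 and self.next[p] != i:
                ok = False
            n = self.next[i]
            if n >= 0 and self.prev[n] != i:
                ok = False
        return ok


def _chain_links(path_id: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sequential prev/next links that break wherever ``path_id`` changes."""
    n = len(path_id)
    prev = np.arange(-1, n - 1, dtype=np.int64)
    nxt = np.arange(1, n + 1, dtype=np.int64)
    nxt[-1] = -1
    brk = np.flatnonzero(path_id[1:] != path_id[:-1])
    nxt[brk] = -1
    prev[brk + 1] = -1
    return prev, nxt
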