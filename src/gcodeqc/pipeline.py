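"""End-to-end comparison pipeline and the repeatability harness.

Stage order: parse -> PC1 -> voxelize/classify -> PC2 (shell) -> PC3 (XY)
-> PC4 (Z) -> calibration split -> registration -> surface metrics ->
layer reconstruction -> volume metrics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from . import correct, gcode, meshio, metrics, reconstruct, register, voxel
from .cloud import StagedPointCloud
from .errors import GCodeQCError
from .fixtures import FixtureScene, SlicingParams, compose_scene, mini_slice
from .metrics import DeviationReport
from .transform import RigidTransform

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline settings, serialized alongside every report for provenance.

    ``sampling_spacing`` defaults to half the voxel size so rasterization
    cannot skip voxels; ``closure_eps`` defaults to a quarter line width.
    """

    voxel_size: float = 0.10
    sampling_spacing: float | None = None
    icp_max_iter: int = 50
    icp_conv: float = 0.02
    closure_eps: float | None = None
    co_dims: tuple = register.CO_DIMS
    default_layer_height: float = 0.20
    default_line_width: float = 0.40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size <= 0 or self.icp_conv <= 0 or self.icp_max_iter <= 0:
            raise ValueError("tolerances must be positive")

    @property
    def spacing(self) -> float:
        return self.sampling_spacing or self.voxel_size / 2.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sampling_spacing"] = self.spacing
        return d

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            data = json.loads(path.read_text())
        return cls(**data)


@dataclass
class CompareResult:
    """Full pipeline output: the deviation report plus every intermediate
    artifact needed for QC or resumption."""

    report: DeviationReport
    transform: RigidTransform
    config: RunConfig
    pc4_model: StagedPointCloud
    pc4_calibration: StagedPointCloud
    tpcm: StagedPointCloud
    recon_mesh: trimesh.Trimesh
    label_map: voxel.VoxelLabelMap
    layer_sets: list
    stage_stats: dict = field(default_factory=dict)

    def report_dict(self) -> dict:
        d = self.report.csv_row()
        d["icp_residual_rms"] = getattr(self.transform, "residual_rms", None)
        d["config"] = self.config.to_dict()
        d["stage_stats"] = {
            k: {kk: vv for kk, vv in v.items() if np.isscalar(vv)}
            for k, v in self.stage_stats.items()
        }
        d["transform"] = self.transform.to_matrix().tolist()
        return d


def correct_cloud(
    tp: gcode.Toolpath, cfg: RunConfig
) -> tuple[StagedPointCloud, voxel.VoxelLabelMap, dict]:
    """Shared front half: PC1 sampling, voxelization and both corrections."""
    h, w = tp.meta.layer_height, tp.meta.line_width
    pc1 = gcode.extract_centerline_points(tp, spacing=cfg.spacing)
    vmap = voxel.classify_labels(voxel.voxelize(pc1, w, h, cfg.voxel_size))
    pc2 = correct.shell_filter(pc1, vmap, w=w, h=h)
    pc3 = correct.xy_correct(pc2, vmap, w, h=h)
    pc4 = correct.z_correct(pc3, vmap, h)
    stats = {"PC2": pc2.stats, "PC3": pc3.stats, "PC4": pc4.stats}
    stats["PC1"] = {"n_points": len(pc1), "n_segments": tp.n_segments}
    return pc4, vmap, stats


def run_compare(
    gcode_src: str | Path,
    ref_mesh: trimesh.Trimesh | str | Path,
    cfg: RunConfig | None = None,
    co_mesh: trimesh.Trimesh | None = None,
) -> CompareResult:
    """Compare the geometry encoded in a G-code file with its reference STL.

    ``gcode_src`` may be a path or raw G-code text; ``ref_mesh`` the
    reference model mesh (path or mesh) *without* the calibration object,
    which defaults to the analytic step solid.
    """
    cfg = cfg or RunConfig()
    if isinstance(ref_mesh, (str, Path)):
        ref_mesh = meshio.read_stl(ref_mesh)
    if co_mesh is None:
        from .fixtures import make_calibration_object

        co_mesh = make_calibration_object()

    text = gcode_src
    if isinstance(gcode_src, Path) or (
        isinstance(gcode_src, str) and "\n" not in gcode_src and Path(gcode_src).exists()
    ):
        text = Path(gcode_src).read_text()

    defaults = gcode.ProcessMeta(
        layer_height=cfg.default_layer_height, line_width=cfg.default_line_width
    )
    tp = gcode.parse_gcode(text, defaults=defaults)
    h, w = tp.meta.layer_height, tp.meta.line_width

    pc4, vmap, stats = correct_cloud(tp, cfg)
    pco, pcm = register.split_calibration(pc4, vmap, co_dims=cfg.co_dims)
    transform = register.register_calibration(
        pco, co_mesh, max_iter=cfg.icp_max_iter, conv=cfg.icp_conv
    )
    tpcm = register.apply_transform(pcm, transform)
    report = metrics.surface_metrics(tpcm, ref_mesh)

    recon, layer_sets = reconstruct.reconstruct_solid(pcm, h, w=w, eps=cfg.closure_eps)
    recon_registered = recon.copy()
    recon_registered.apply_transform(transform.to_matrix())
    report = metrics.volume_difference(recon_registered, ref_mesh, report)

    return CompareResult(
        report=report, transform=transform, config=cfg,
        pc4_model=pcm, pc4_calibration=pco, tpcm=tpcm,
        recon_mesh=recon_registered, label_map=vmap, layer_sets=layer_sets,
        stage_stats=stats,
    )


def run_scene(scene: FixtureScene, cfg: RunConfig | None = None) -> CompareResult:
    """Slice a fixture scene with the mini-slicer and run the comparison
    against the scene's own reference model mesh."""
    return run_compare(
        mini_slice(scene), scene.model_mesh, cfg=cfg, co_mesh=scene.co_mesh
    )


METRIC_KEYS = ("msd", "rms", "d_min", "d_max", "volume_diff_rel")


def run_repeatability(
    model_mesh: trimesh.Trimesh,
    placements: list[RigidTransform],
    cfg: RunConfig | None = None,
    params: SlicingParams | None = None,
) -> dict:
    """Slice the same model at several placements and report each metric's
    deviation from its mean across placements.

    Returns ``{"runs": [...], "deviation_from_mean": {metric: [...]},
    "failed": [...]}`` — the deviation table is what a repeatability plot
    shows; with the deterministic mini-slicer every entry is 0.
    """
    if len(placements) < 2:
        raise GCodeQCError("repeatability needs at least 2 placements")
    runs, failed = [], []
    for i, placement in enumerate(placements):
        try:
            scene = compose_scene(model_mesh, placement, params=params)
            res = run_scene(scene, cfg)
            runs.append({k: getattr(res.report, k) for k in METRIC_KEYS})
        except GCodeQCError as exc:  # keep going, mark the failure
            log.warning("placement %d failed: %s", i, exc)
            failed.append({"placement": i, "error": str(exc)})
            runs.append(None)
    ok = [r for r in runs if r is not None]
    if not ok:
        raise GCodeQCError("every placement failed")
    means = {k: float(np.mean([r[k] for r in ok])) for k in METRIC_KEYS}
    deviations = {
        k: [None if r is None else r[k] - means[k] for r in runs]
        for k in METRIC_KEYS
    }
    return {"runs": runs, "mean": means, "deviation_from_mean": deviations,
            "failed": failed}
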