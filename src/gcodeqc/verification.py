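"""Self-verification harnesses: the experiments that establish the
pipeline's own accuracy, independent of any reference data.

These mirror the framework's validation protocol at fixture scale:

* deposition-plane alignment — after the Z correction, corrected points
  must lie on slicer-defined deposition planes (multiples of the layer
  height) to within the voxel quantization bound;
* voxel-size sensitivity — halving the voxel size must not change the
  pipeline MSD appreciably, showing the 0.10 mm default grid is adequate;
* registration recovery — known rigid placements of a scene must be
  recovered by the calibration-object registration, and the residual
  registration error must have negligible impact on the surface metrics;
* repeatability — identical inputs must produce identical reports.
"""

from __future__ import annotations

import numpy as np

from . import gcode, pipeline, register
from .fixtures import SlicingParams, compose_scene, make_box, make_lbeam, mini_slice
from .transform import RigidTransform


def deposition_plane_fraction(z_values: np.ndarray, h: float, tol: float = 0.10) -> float:
    """Percentage of Z values within ``tol`` mm of a deposition plane.

    The plane grid is the set of layer-height multiples (the down-shifted
    and superior-edge positions both lie on it).
    """
    z = np.asarray(z_values, dtype=float)
    dist = np.abs(z - np.round(z / h) * h)
    return float((dist <= tol + 1e-12).mean() * 100.0)


def z_alignment_experiment(
    seed: int = 0, cfg: pipeline.RunConfig | None = None
) -> dict:
    """Slice a 20 x 20 x 2 mm box with the calibration object, run the
    corrections, and measure the fraction of PC4 points on deposition
    planes.  Returns the percentage and the problem size."""
    cfg = cfg or pipeline.RunConfig(seed=seed)
    scene = compose_scene(make_box((20.0, 20.0, 2.0)), seed=seed,
                          params=SlicingParams(seed=seed))
    tp = gcode.parse_gcode(mini_slice(scene))
    pc4, _, _ = pipeline.correct_cloud(tp, cfg)
    frac = deposition_plane_fraction(pc4.points[:, 2], tp.meta.layer_height)
    return {"percent_on_plane": frac, "n_points": len(pc4)}


def voxel_sensitivity_experiment(
    seed: int = 0, voxel_sizes: tuple[float, float] = (0.10, 0.05)
) -> dict:
    """Run the full comparison at two voxel sizes on two fixture models and
    report the absolute MSD difference per model (and the maximum)."""
    models = {
        "box_20x20x5": make_box((20.0, 20.0, 5.0)),
        "lbeam_20x10x5": make_lbeam(20.0, 10.0, 5.0),
    }
    diffs = {}
    n_total = 0
    for name, mesh in models.items():
        msds = []
        for vs in voxel_sizes:
            cfg = pipeline.RunConfig(voxel_size=vs, seed=seed)
            scene = compose_scene(mesh, seed=seed, params=SlicingParams(seed=seed))
            res = pipeline.run_scene(scene, cfg)
            msds.append(res.report.msd)
            n_total += res.report.n_points
        diffs[name] = abs(msds[0] - msds[1])
    return {"msd_abs_diff": diffs, "max_abs_diff": max(diffs.values()),
            "n_points": n_total}


def random_placements(
    n: int, seed: int, max_translation: float = 150.0, max_rotation_deg: float = 5.0
) -> list[RigidTransform]:
    """Seeded in-plane rigid placements (XY translation, Z rotation), the
    degrees of freedom a slicer's build-plate frame actually has."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        t = np.append(rng.uniform(-max_translation, max_translation, size=2), 0.0)
        ang = rng.uniform(-max_rotation_deg, max_rotation_deg)
        out.append(RigidTransform.from_rotvec_deg([0, 0, 1], ang, t))
    return out


def registration_recovery_experiment(
    n_placements: int = 20,
    seed: int = 0,
    model_extents: tuple = (10.0, 10.0, 2.0),
    cfg: pipeline.RunConfig | None = None,
) -> dict:
    """Recover seeded rigid placements through the full correction +
    registration chain.

    For each placement the scene is sliced, corrected, split and
    registered; the recovered transform is compared with the ground truth
    and the model cloud's MSD is evaluated under both, giving the metric
    perturbation the residual registration error induces.
    """
    from .metrics import surface_metrics_points

    cfg = cfg or pipeline.RunConfig(seed=seed)
    model = make_box(model_extents)
    trans_err, rot_err, msd_pert = [], [], []
    for placement in random_placements(n_placements, seed):
        scene = compose_scene(model, placement, params=SlicingParams(seed=seed))
        tp = gcode.parse_gcode(mini_slice(scene))
        pc4, vmap, _ = pipeline.correct_cloud(tp, cfg)
        pco, pcm = register.split_calibration(pc4, vmap, co_dims=cfg.co_dims)
        recovered = register.register_calibration(
            pco, scene.co_mesh, max_iter=cfg.icp_max_iter, conv=cfg.icp_conv
        )
        truth = placement.inverse()
        delta = recovered.compose(truth.inverse())
        trans_err.append(np.abs(recovered.translation - truth.translation))
        rot_err.append(delta.rotation_angle_deg())
        msd_rec = surface_metrics_points(
            recovered.apply(pcm.points), scene.model_mesh
        ).msd
        msd_true = surface_metrics_points(
            truth.apply(pcm.points), scene.model_mesh
        ).msd
        msd_pert.append(abs(msd_rec - msd_true))
    trans_err = np.asarray(trans_err)
    return {
        "n_placements": n_placements,
        "max_translation_error": float(trans_err.max()),
        "mean_abs_translation_xy": [
            float(trans_err[:, 0].mean()), float(trans_err[:, 1].mean())
        ],
        "max_rotation_error_deg": float(np.max(rot_err)),
        "max_msd_perturbation": float(np.max(msd_pert)),
    }
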