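"""End-to-end orchestration of the calibration/reconstruction protocol.

The full chain, for one acquisition:

    phantom calibration scan  ->  per-view geometric calibration
    patient projections       ->  preliminary FDK
    surface mask              ->  3-D registration to the preliminary FDK
                              ->  per-view refinement of H, V, skew
                              ->  FDK (refined) and surface-constrained SCoLD
                              ->  SAI / LiVA metrics vs a reference volume

``run_pipeline`` executes the chain from a :class:`PipelineConfig`;
``simulate_study`` fabricates a complete synthetic study (calibration scan,
patient scan with per-view perturbations, mask, reference) so the pipeline
is exercisable without any external data.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as cio
from .calibration import calibrate_scan
from .containers import ProjectionSet, SurfaceMask, Volume
from .geometry import (
    DetectorSpec,
    GeometryPerturbation,
    Trajectory,
    make_circular_trajectory,
    perturb_trajectory,
    save_geometry,
)
from .metrics import evaluate, roi_from_reference
from .phantoms import (
    CalibPhantomSpec,
    make_digital_sample,
    simulate_calib_scan,
    simulate_scan,
)
from .recon import SCoLDParams, fdk_reconstruct, scold_reconstruct
from .refine import refine_scan

__all__ = ["PipelineConfig", "StudyData", "simulate_study", "run_pipeline"]

log = logging.getLogger("carmtomo")


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run (fully serializable)."""

    # acquisition geometry
    n_views: int = 25
    span: float = 120.0
    sdd: float = 1250.0
    sod: float = 625.0
    det_n_h: int = 444
    det_n_v: int = 540
    det_pixel: float = 0.8
    # reconstruction grid
    grid_size: int = 96
    voxel_size: float = 1.5
    recon_bin: int = 2  # detector rebinning factor for reconstruction
    # phantom / model parameters
    phantom: dict = field(default_factory=dict)
    scold: dict = field(default_factory=dict)
    # simulation settings for the demo path
    seed: int = 0
    perturb_dh: float = 8.0
    perturb_dv: float = 8.0
    perturb_ds: float = 2.0
    noise: str | None = None
    i0: float = 1e5
    # inputs (optional file paths; when None the study is simulated)
    projections_path: str | None = None
    calib_path: str | None = None
    mask_path: str | None = None
    reference_path: str | None = None
    log_level: str = "INFO"

    def detector(self) -> DetectorSpec:
        return DetectorSpec(self.det_n_h, self.det_n_v, self.det_pixel)

    def phantom_spec(self) -> CalibPhantomSpec:
        return CalibPhantomSpec(**self.phantom)

    def scold_params(self) -> SCoLDParams:
        return SCoLDParams(**self.scold)

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        bad = set(doc) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)


@dataclass
class StudyData:
    """One acquisition: projections, calibration scan, mask, ground truth."""

    projections: ProjectionSet
    calib_projections: ProjectionSet
    mask: SurfaceMask
    reference: Volume
    true_trajectory: Trajectory
    perturbation: GeometryPerturbation


def simulate_study(cfg: PipelineConfig) -> StudyData:
    """Fabricate a full synthetic acquisition.

    The source/detector poses of the patient scan are perturbed per view
    (mechanical non-repeatability); the calibration scan is acquired with
    the *nominal* poses, so the pipeline has something real to refine.
    """
    det = cfg.detector()
    nominal = make_circular_trajectory(
        cfg.n_views, cfg.span, cfg.sdd, cfg.sod, det
    )
    rng_seed = cfg.seed % (2**31)
    pert = GeometryPerturbation.random(
        cfg.n_views, cfg.perturb_dh, cfg.perturb_dv, cfg.perturb_ds,
        seed=rng_seed,
    )
    traj_true = perturb_trajectory(nominal, pert)
    sample = make_digital_sample(
        "ellipsoid-limb", cfg.grid_size, cfg.voxel_size, seed=rng_seed
    )
    projections = simulate_scan(
        sample.volume, traj_true, noise=cfg.noise, i0=cfg.i0,
        seed=rng_seed + 1,
    )
    calib_projs, _ = simulate_calib_scan(cfg.phantom_spec(), nominal)
    return StudyData(
        projections=projections,
        calib_projections=calib_projs,
        mask=sample.support,
        reference=sample.volume,
        true_trajectory=traj_true,
        perturbation=pert,
    )


def _load_or_simulate(cfg: PipelineConfig) -> StudyData:
    if cfg.projections_path is None:
        log.info("no input paths given: simulating a synthetic study")
        return simulate_study(cfg)
    projections = cio.read_projections(cfg.projections_path)
    calib = (
        cio.read_projections(cfg.calib_path) if cfg.calib_path else None
    )
    mask = cio.read_mask(cfg.mask_path) if cfg.mask_path else None
    reference = (
        cio.read_volume(cfg.reference_path) if cfg.reference_path else None
    )
    return StudyData(
        projections=projections,
        calib_projections=calib,
        mask=mask,
        reference=reference,
        true_trajectory=None,
        perturbation=None,
    )


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute calibrate -> FDK -> refine -> FDK/SCoLD -> metrics.

    All intermediates are written under ``outdir``; the returned dict maps
    stage names to in-memory results.  Stages degrade gracefully: without a
    calibration scan the nominal geometry is used; without a mask the SCoLD
    stage is skipped (with an explicit notice) and FDK is still produced.
    Identical config + seed reproduce bit-identical geometry and metrics
    files.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level, logging.INFO))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = cio.config_hash(cfg.as_dict())
    cfg.to_yaml(outdir / "config.yaml")
    results: dict = {"config_hash": chash}
    t_start = time.time()
    study = _load_or_simulate(cfg)
    shape = (cfg.grid_size,) * 3
    det = study.projections.detector

    # --- stage 1: geometric calibration -------------------------------
    if study.calib_projections is not None:
        t0 = time.time()
        calib_traj, calib_report = calibrate_scan(
            study.calib_projections, cfg.phantom_spec()
        )
        log.info("calibration: %d views in %.1fs",
                 len(calib_traj), time.time() - t0)
        results["calibration_report"] = calib_report
    else:
        log.warning("no calibration scan: using nominal geometry")
        calib_traj = study.projections.trajectory
    save_geometry(calib_traj, outdir / f"geometry_initial_{chash}.json")
    results["trajectory_initial"] = calib_traj

    # --- stage 2: adaptive refinement ----------------------------------
    if study.mask is not None:
        t0 = time.time()
        refined_traj, refine_report = refine_scan(
            study.projections, study.mask, calib_traj
        )
        log.info("refinement in %.1fs", time.time() - t0)
        results["refine_report"] = refine_report
    else:
        log.warning("no surface mask: refinement skipped")
        refined_traj = calib_traj
    save_geometry(refined_traj, outdir / f"geometry_refined_{chash}.json")
    results["trajectory_refined"] = refined_traj

    # --- stage 3: reconstructions --------------------------------------
    from .recon import bin_projections

    proj_recon = bin_projections(
        ProjectionSet(
            study.projections.data, refined_traj, dict(study.projections.meta)
        ),
        cfg.recon_bin,
    )
    t0 = time.time()
    fdk = fdk_reconstruct(proj_recon, shape, cfg.voxel_size)
    log.info("FDK in %.1fs", time.time() - t0)
    cio.write_volume(fdk, outdir / f"fdk_{chash}.mha")
    results["fdk"] = fdk
    if study.mask is not None:
        t0 = time.time()
        scold = scold_reconstruct(
            proj_recon, shape, cfg.voxel_size, study.mask,
            cfg.scold_params(),
        )
        log.info("SCoLD in %.1fs", time.time() - t0)
        cio.write_volume(scold.volume_masked, outdir / f"scold_{chash}.mha")
        results["scold"] = scold
        np.savetxt(
            outdir / f"scold_convergence_{chash}.csv",
            np.column_stack([scold.data_residuals, scold.cg_iterations]),
            delimiter=",", header="data_residual,cg_iterations", comments="",
        )
    else:
        log.warning("no surface mask: SCoLD stage skipped, FDK only")
        results["scold"] = None

    # --- stage 4: metrics ----------------------------------------------
    if study.reference is not None:
        roi = roi_from_reference(study.reference)
        rows = [("fdk",) + _metric_row(fdk, study.reference, roi)]
        if results["scold"] is not None:
            rows.append(
                ("scold",)
                + _metric_row(
                    results["scold"].volume_masked, study.reference, roi
                )
            )
        with open(outdir / f"metrics_{chash}.csv", "w") as fh:
            fh.write("method,sai,liva,roi_voxels\n")
            for name, s, l, nvox in rows:
                fh.write(f"{name},{s:.10g},{l:.10g},{nvox}\n")
        results["metrics"] = {
            name: {"sai": s, "liva": l} for name, s, l, _ in rows
        }
    log.info("pipeline done in %.1fs", time.time() - t_start)
    return results


def _metric_row(vol, reference, roi):
    rep = evaluate(vol, reference, roi)
    return rep.sai, rep.liva, rep.roi_voxels
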