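"""End-to-end pipeline: phantom -> simulation -> scaling -> reconstruction -> report.

Driven by a YAML config; every stage failure is re-raised with the stage
name so batch runs fail loudly and localizably.  Deterministic under the
configured seed.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .geometry import BeamSetup, load_spectrum, make_analytic_spectrum
from .materials import build_material_library, absorption_map, labels_to_density
from .metrics import MeasurementSet, compare_measurements, mape, sample_dose_at_points, slice_organ_dose
from .phantom import BRAIN, make_head_phantom
from .resample import DownsampleSpec, _nn_upsample_slice, reconstruct_from_simulation
from .volume import ScalarVolume
from .transport import estimate_uncertainty, scale_to_air_kerma, simulate
from .volume import read_volume, write_volume

log = logging.getLogger("dosekit.pipeline")

__all__ = ["run_pipeline", "PipelineError", "load_config", "build_setup"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class _Stage:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        log.info("stage: %s", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            raise PipelineError(f"stage '{self.name}' failed: {exc}") from exc
        return False


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def build_setup(geo: dict) -> BeamSetup:
    """Construct a BeamSetup from the geometry section of a config."""
    if geo.get("spectrum_csv"):
        spectrum = load_spectrum(geo["spectrum_csv"], kvp=geo.get("kvp"))
    else:
        spectrum = make_analytic_spectrum(
            float(geo.get("kvp", 120.0)),
            filtration_mm=float(geo.get("filtration_mm_cu", 0.0)),
        )
    return BeamSetup(
        primary_angle=float(geo.get("primary_angle_deg", 0.0)),
        sod=float(geo.get("sod_mm", 800.0)),
        sid=float(geo.get("sid_mm", 1200.0)),
        opening_phi=float(geo.get("opening_phi_deg", 4.5)),
        opening_theta=float(geo.get("opening_theta_deg", 1.6)),
        spectrum=spectrum,
        isocenter=np.asarray(geo.get("isocenter_mm", (0.0, 0.0, 0.0)), float),
    )


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> Path:
    """Execute the full workflow described by a YAML config; returns the
    artifact directory (volumes, report.json, optional per-point CSV)."""
    t0 = time.time()
    cfg = load_config(config_path)
    out = Path(out_dir or cfg.get("output_dir", "dosekit_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))

    with _Stage("materials"):
        lib = build_material_library()

    with _Stage("phantom"):
        ph = cfg.get("phantom", {})
        if "path" in ph:
            labels = read_volume(ph["path"])
        else:
            labels = make_head_phantom(
                int(ph.get("n_xy", 64)),
                int(ph.get("n_z", 8)),
                tuple(ph.get("spacing", (1.0, 1.0, 5.0))),
                seed=int(ph.get("seed", 0)),
            )
        write_volume(labels, out / "labels.mhd")

    with _Stage("geometry"):
        setup = build_setup(cfg.get("geometry", {}))

    sim = cfg.get("simulation", {})
    n_histories = int(sim.get("n_histories", 100_000))
    n_batches = int(sim.get("n_batches", 5))
    s = int(sim.get("downsample_s", 1))

    with _Stage("simulation"):
        spec = DownsampleSpec(s=s, eps=sim.get("eps"))
        recon, coarse = reconstruct_from_simulation(
            labels, lib, setup, spec, n_histories, seed=seed, n_batches=n_batches
        )

    with _Stage("air-kerma scaling"):
        kair = cfg.get("air_kerma_mgy")
        factor = 1.0
        if kair is not None:
            factor = float(kair) / coarse.ref_point_air_kerma
            coarse = scale_to_air_kerma(coarse, float(kair))
            recon = recon.with_values(recon.values * factor)

    with _Stage("artifacts"):
        write_volume(coarse.primary_dose, out / "primary_dose.mhd")
        write_volume(coarse.scatter_dose, out / "scatter_dose.mhd")
        write_volume(coarse.total_dose, out / "total_dose.mhd")
        write_volume(estimate_uncertainty(coarse), out / "uncertainty_2sigma_pct.mhd")
        write_volume(recon, out / "reconstructed_dose.mhd")

    with _Stage("metrics"):
        report = {
            "dosekit_version": __version__,
            "config": cfg,
            "seed": seed,
            "n_histories": n_histories,
            "downsample_s": s,
            "ref_point_air_kerma_mGy": coarse.ref_point_air_kerma,
            "air_kerma_scale_factor": factor,
            "runtime_s": None,  # filled below
        }
        organ = slice_organ_dose(recon, labels, BRAIN)
        report["slice_brain_dose_mGy"] = {int(k): v for k, v in organ.items()}

        # consistency metric: reconstruction vs block-replicated coarse dose
        nz, ny, nx = labels.shape
        up = np.stack([
            _nn_upsample_slice(coarse.total_dose.values[k], (ny, nx), s)
            for k in range(nz)
        ])
        air = lib.label_for("air")
        sel = (labels.labels != air) & (up > 0)
        report["mape_recon_vs_coarse_pct"] = (
            mape(recon, ScalarVolume(up, labels.spacing, labels.origin), sel)
            if sel.any() else None
        )

        meas_path = cfg.get("measurements_csv")
        if meas_path:
            measured = MeasurementSet.from_csv(meas_path)
            simulated = sample_dose_at_points(recon, measured)
            comparison = compare_measurements(simulated, measured)
            comparison.points.to_csv(out / "points.csv", index=False)
            report["measurement_comparison"] = comparison.to_dict()

    report["runtime_s"] = round(time.time() - t0, 3)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    log.info("pipeline finished in %.1f s -> %s", report["runtime_s"], out)
    return out
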