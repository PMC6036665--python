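"""End-to-end reproducible runs: simulate -> reconstruct -> fuse -> measure.

A run is described by a :class:`RunConfig` (spectrometer preset, phantom,
noise, seed, stages); all randomness flows through the single seed, so the
same config yields bit-identical outputs and manifest checksums.  Rasters
are persisted as TIFF, tables as CSV, and every run writes a JSON manifest
listing inputs, outputs and SHA-256 checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import biometry, fusion, optics, phantom as phantom_mod, recon, simulator
from .errors import DomainError

STAGES = ("simulate", "reconstruct", "fuse", "measure", "dynamics")


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    system: str = "system3"
    seed: int = 0
    output_dir: str = "asoct-run"
    stages: tuple = ("simulate", "reconstruct", "fuse", "measure")
    phantom_file: str | None = None  # YAML phantom (+ optional trajectory)
    iol: bool = False
    n_alines: int = 1024
    dynamics_n_alines: int = 256
    noise: simulator.NoiseParams | None = field(default_factory=simulator.NoiseParams)
    meridian: str = "horizontal"
    state: str = "relaxed"

    def __post_init__(self):
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise DomainError(f"unknown stages {bad}; valid: {STAGES}")
        order = [STAGES.index(s) for s in self.stages]
        if order != sorted(order):
            raise DomainError("stages must follow simulate->reconstruct->fuse->measure->dynamics")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        noise = doc.pop("noise", "default")
        cfg = cls(**doc)
        if noise is None:
            cfg.noise = None
        elif isinstance(noise, dict):
            cfg.noise = simulator.NoiseParams(**noise)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_phantom(config: RunConfig):
    if config.phantom_file:
        return phantom_mod.load_phantom(config.phantom_file)
    ph = phantom_mod.default_iol_phantom() if config.iol else phantom_mod.default_phantom()
    return ph, phantom_mod.default_trajectory(ph)


def save_raw_pair(path, frame1: simulator.RawFrame, frame2: simulator.RawFrame):
    """Persist a raw frame pair as a two-page float32 TIFF."""
    tifffile.imwrite(
        path,
        np.stack([frame1.interferograms, frame2.interferograms]).astype(np.float32),
    )


def save_raster_tiff(path, raster_db: np.ndarray):
    """Persist a dB raster as 16-bit TIFF (linearly scaled) + return scaling."""
    lo, hi = float(raster_db.min()), float(raster_db.max())
    scale = (raster_db - lo) / max(hi - lo, 1e-9)
    tifffile.imwrite(path, (scale * 65535).astype(np.uint16))
    return {"db_min": lo, "db_max": hi}


def save_png_preview(path, raster_db: np.ndarray):
    lo, hi = np.percentile(raster_db, [5, 99.9])
    img = np.clip((raster_db - lo) / max(hi - lo, 1e-9), 0, 1)
    iio.imwrite(path, (img * 255).astype(np.uint8))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages and return the manifest (also written
    to ``manifest.json`` in the output directory)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    spectrometer = optics.system_preset(config.system)
    source = optics.SourceSpectrum()
    eye, trajectory = _load_phantom(config)
    arm = simulator.recommended_arm_geometry(eye)
    manifest = {
        "seed": config.seed,
        "system": config.system,
        "stages": list(config.stages),
        "arm_opd_offset_mm": arm.opd_offset,
        "outputs": {},
        "failed_stage": None,
    }

    def record(name, path):
        manifest["outputs"][name] = {
            "path": str(path.name),
            "sha256": _sha256(path),
        }

    frames = fused = None
    try:
        if "simulate" in config.stages:
            frames = simulator.simulate_bscan_pair(
                eye, spectrometer, source, arm,
                n_alines=config.n_alines, noise=config.noise, seed=config.seed,
            )
            p = out / "raw_pair.tiff"
            save_raw_pair(p, *frames)
            record("raw_pair", p)
            meta = {
                "system": config.system,
                "seed": config.seed,
                "n_alines": config.n_alines,
                "arm_geometry": {"opd_offset": arm.opd_offset, "arm1_z0": arm.arm1_z0},
                "phantom": phantom_mod.phantom_to_dict(eye),
            }
            p = out / "raw_pair.json"
            p.write_text(json.dumps(meta, indent=2))
            record("raw_meta", p)

        bscans = None
        if "reconstruct" in config.stages:
            bscans = [recon.reconstruct_frame(f, spectrometer, source) for f in frames]
            for f in bscans:
                p = out / f"bscan_arm{f.arm_id}.tiff"
                tifffile.imwrite(p, f.raster.astype(np.float32))
                record(f"bscan_arm{f.arm_id}", p)

        if "fuse" in config.stages:
            zmax = optics.max_scan_depth(source.center_wavelength, spectrometer.delta_lambda)
            fused = fusion.fuse_pair(bscans[0], bscans[1], arm, z_max=zmax)
            p = out / "fused.tiff"
            scale = save_raster_tiff(p, fused.raster)
            record("fused", p)
            save_png_preview(out / "fused_preview.png", fused.raster)
            record("fused_preview", out / "fused_preview.png")
            side = {
                "transform": {
                    "rotation_deg": fused.transform.rotation,
                    "translation_px": list(fused.transform.translation),
                    "correlation": fused.transform.correlation,
                },
                "combined_dropoff_db": fused.combined_dropoff_db,
                "tiff_scaling": scale,
            }
            p = out / "fused.json"
            p.write_text(json.dumps(side, indent=2))
            record("fused_meta", p)

        if "measure" in config.stages:
            result, _, _ = biometry.biometry_from_fused(
                fused, eye.media, meridian=config.meridian, state=config.state
            )
            p = out / "biometry.csv"
            pd.DataFrame([result.as_dict()]).to_csv(p, index=False)
            record("biometry", p)

        if "dynamics" in config.stages:
            df, fits = run_dynamics(
                eye, trajectory, spectrometer, source,
                n_alines=config.dynamics_n_alines, noise=config.noise, seed=config.seed,
            )
            p = out / "dynamics.csv"
            df.to_csv(p, index=False)
            record("dynamics", p)
            p = out / "dynamics_fits.csv"
            fits.to_csv(p, index=False)
            record("dynamics_fits", p)
    except Exception as exc:
        manifest["failed_stage"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def run_dynamics(
    eye,
    trajectory,
    spectrometer,
    source,
    n_alines: int = 256,
    noise: simulator.NoiseParams | None = None,
    seed: int = 0,
):
    """Image every frame of an accommodation trajectory and fit sigmoids.

    Returns ``(series, fits)`` DataFrames: per-frame CCT/ACD/CLT and the
    fitted sigmoid parameters for ACD and CLT.
    """
    arm = simulator.recommended_arm_geometry(eye)
    zmax = optics.max_scan_depth(source.center_wavelength, spectrometer.delta_lambda)
    rows = []
    for i, (t, ph_t) in enumerate(phantom_mod.sample_trajectory(eye, trajectory)):
        frames = simulator.simulate_bscan_pair(
            ph_t, spectrometer, source, arm, n_alines=n_alines, noise=noise, seed=seed + i
        )
        bscans = [recon.reconstruct_frame(f, spectrometer, source) for f in frames]
        fused = fusion.fuse_pair(bscans[0], bscans[1], arm, z_max=zmax, rotation_span=0.0)
        res, _, _ = biometry.biometry_from_fused(fused, eye.media)
        rows.append({"t": t, "CCT": res.cct, "ACD": res.acd, "CLT": res.clt})
    series = pd.DataFrame(rows)
    fit_rows = []
    for qty in ("ACD", "CLT"):
        try:
            f = biometry.fit_sigmoid(series["t"].values, series[qty].values, seed=seed)
            fit_rows.append(
                {
                    "quantity": qty,
                    "baseline": f.baseline,
                    "amplitude": f.amplitude,
                    "t0": f.t0,
                    "k": f.k,
                    "residual_rms": f.residual_rms,
                }
            )
        except Exception as exc:  # a flat series (IOL CLT) is not an error
            fit_rows.append({"quantity": qty, "error": str(exc)})
    return series, pd.DataFrame(fit_rows)


def characterize_systems(
    names=("system1", "system2", "system3"),
    depths=None,
    output_dir: str = "asoct-characterize",
    seed: int = 0,
    noise: simulator.NoiseParams | None = None,
):
    """Roll-off curves + performance figures for the named presets."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    source = optics.SourceSpectrum()
    perf_rows = []
    for name in names:
        cfg = optics.system_preset(name)
        perf = optics.performance_figures(cfg, source)
        perf_rows.append(perf.as_dict())
        zmax = perf.max_depth_air
        d = depths if depths is not None else np.linspace(0.5, 0.95 * zmax, 12)
        curve = recon.rolloff_experiment(cfg, source, d, seed=seed, noise=noise)
        pd.DataFrame(
            {"depth_mm": curve.depths, "sensitivity_db": curve.sensitivities}
        ).to_csv(out / f"rolloff_{name}.csv", index=False)
    pd.DataFrame(perf_rows).to_csv(out / "performance.csv", index=False)
    return out
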