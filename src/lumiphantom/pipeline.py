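"""End-to-end orchestration: simulate -> synthesize -> extract -> bin ->
fit -> predict, with config validation and a reproducibility manifest.

The default configuration reproduces the study conditions at desk scale:
2-mm top-hat spot at 2/3/4/5 J/cm^2 on the characterized phantom
(mua = 0.348 mm^-1, mus' = 2.81 mm^-1, g = 0.86, n = 1.4), five replicate
image pairs per fluence, the +10 / 0.1-mm segmentation rule, the 0.19-mm
surface exclusion, 0.1-J/cm^2 fluence bins and the per-fluence fit ranges.
"""

from __future__ import annotations

import copy
import time
from pathlib import Path

import numpy as np

from . import __version__, io
from .depth import depth_tables, ratio_vs_depth, threshold_depth
from .dose_response import (DEFAULT_FIT_RANGES, FitRange, SigmoidParams,
                            align_by_centroid, average_curves,
                            cavitation_curve, fit_sigmoid, pool_curves,
                            resample_axial_slice)
from .extraction import extract_cavities
from .mc import (BeamSpec, GridSpec, OpticalProperties, extract_axial_slice,
                 scale_to_absolute, simulate_fluence)
from .synth import SynthSpec, generate_experiment, mean_cavity_area_px

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_full_pipeline",
           "StageError"]

DEFAULT_CONFIG: dict = {
    "optical": {"mua": 0.348, "mus_prime": 2.81, "g": 0.86, "n": 1.4},
    "beam": {"spot_mm": 2.0, "fluences_Jcm2": [2.0, 3.0, 4.0, 5.0]},
    "grid": {"voxel_size_mm": 0.05, "depth_mm": 5.5, "width_mm": None},
    "mc": {"n_photons": 1_000_000, "seed": 1, "slice_smoothing_mm": 0.1},
    "synth": {"n_replicates": 5, "pixel_size_mm": 0.01,
              "jitter_fraction": 0.0, "image_depth_mm": 4.0,
              "sigmoid": {"L": 0.24, "x0": 1.37, "k": 2.0, "b": -0.005}},
    "extraction": {"threshold": 10.0, "radius_mm": 0.1,
                   "exclusion_mm": 0.19},
    "curve": {"bin_width_Jcm2": 0.1},
    "predict": {"spots_mm": [2.0, 3.0, 5.0], "spot_fluence_Jcm2": 2.0,
                "n_photons": 400_000},
}

#: keys the user config must state explicitly (no silent default)
_REQUIRED = (("beam", "spot_mm"),)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the partial
    manifest accumulated so far."""

    def __init__(self, stage: str, cause: BaseException, manifest: dict):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.manifest = manifest


def validate_config(config: dict) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys and
    requiring the explicitly-stated keys. Returns the merged config."""

    def merge(defaults: dict, user: dict, path: str) -> dict:
        out = copy.deepcopy(defaults)
        for key, val in user.items():
            if key not in defaults:
                raise ValueError(f"unknown config key: {path}{key}")
            if isinstance(defaults[key], dict) and isinstance(val, dict):
                out[key] = merge(defaults[key], val, f"{path}{key}.")
            else:
                out[key] = val
        return out

    merged = merge(DEFAULT_CONFIG, config or {}, "")
    for section, key in _REQUIRED:
        if key not in (config or {}).get(section, {}):
            raise ValueError(f"missing required config key: {section}.{key}")
    return merged


def _image_shape(cfg: dict, grid: GridSpec) -> tuple[int, int]:
    ps = cfg["synth"]["pixel_size_mm"]
    rows = int(round(cfg["synth"]["image_depth_mm"] / ps))
    cols = int(round(grid.nx * grid.voxel_size / ps))
    return rows, cols


def run_full_pipeline(config: dict, outdir: str | Path | None = None) -> dict:
    """Execute the full in-silico experiment; returns
    ``{"summary": ..., "manifest": ...}``.

    The summary holds per-fluence curves, the pooled sigmoid fit (and a
    full-range fit for comparison) and predicted threshold depths; the
    manifest records config hash, per-stage seeds and written files so a
    rerun reproduces the summary bit-identically.
    """
    cfg = validate_config(config)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": io.config_hash(cfg),
                      "tool_version": __version__,
                      "seeds": {}, "files": {},
                      "started_at": time.strftime("%Y-%m-%dT%H:%M:%S")}
    summary: dict = {"config_hash": manifest["config_hash"]}
    stage = "configure"
    try:
        props = OpticalProperties.from_reduced(
            mua=cfg["optical"]["mua"], mus_prime=cfg["optical"]["mus_prime"],
            g=cfg["optical"]["g"], n=cfg["optical"]["n"])
        grid = GridSpec.for_beam(cfg["beam"]["spot_mm"],
                                 voxel_size=cfg["grid"]["voxel_size_mm"],
                                 depth=cfg["grid"]["depth_mm"],
                                 width=cfg["grid"]["width_mm"])
        seed = int(cfg["mc"]["seed"])
        manifest["seeds"]["mc"] = seed

        stage = "simulate"
        fmap_rel = simulate_fluence(
            props, BeamSpec(cfg["beam"]["spot_mm"],
                            cfg["beam"]["fluences_Jcm2"][0]),
            grid, int(cfg["mc"]["n_photons"]), seed)
        slice_rel = extract_axial_slice(fmap_rel)
        # The reference maps this emulates are effectively noise-free
        # (1e9-photon production runs); denoise the desk-scale slice so
        # per-voxel MC noise does not leak into the dose-response. The same
        # smoothed slice feeds both image synthesis and fluence binning.
        smooth_mm = cfg["mc"]["slice_smoothing_mm"]
        if smooth_mm and smooth_mm > 0:
            from scipy.ndimage import gaussian_filter
            slice_rel = gaussian_filter(slice_rel,
                                        sigma=smooth_mm / grid.voxel_size)
        if out is not None:
            io.save_fluence_map(fmap_rel, out / "fluence_relative.tif")
            io.save_axial_slice(slice_rel, out / "axial_slice_relative.tif")
            manifest["files"]["fluence_relative"] = "fluence_relative.tif"

        stage = "synthesize"
        sig = cfg["synth"]["sigmoid"]
        spec = SynthSpec(
            sigmoid=SigmoidParams(L=sig["L"], x0=sig["x0"], k=sig["k"],
                                  b=sig["b"]),
            fluence_jitter_fraction=cfg["synth"]["jitter_fraction"],
            pixel_size=cfg["synth"]["pixel_size_mm"])
        shape = _image_shape(cfg, grid)
        slices_abs = {}
        for f0 in cfg["beam"]["fluences_Jcm2"]:
            slices_abs[f0] = resample_axial_slice(
                slice_rel * f0, grid.voxel_size, shape, spec.pixel_size,
                surface_row=spec.surface_row)
        synth_seed = (seed + 1_000_003) % (2**31 - 1)
        manifest["seeds"]["synth"] = synth_seed
        exp = generate_experiment(spec, slices_abs,
                                  cfg["synth"]["n_replicates"], synth_seed)
        manifest["synth_manifest"] = exp["manifest"]

        stage = "extract"
        excl_rows = int(np.ceil(cfg["extraction"]["exclusion_mm"]
                                / spec.pixel_size))
        per_f0_curves: dict[float, list] = {f: [] for f in slices_abs}
        mask_px_counts = []
        for pair in exp["pairs"]:
            mask = extract_cavities(
                pair["post"], pair["pre"],
                threshold=cfg["extraction"]["threshold"],
                radius=cfg["extraction"]["radius_mm"],
                exclusion_depth=cfg["extraction"]["exclusion_mm"])
            mask_px_counts.append(int(mask.mask.sum()))
            fl_img, _ = align_by_centroid(mask, slice_rel * pair["f0"],
                                          grid.voxel_size)
            curve = cavitation_curve(mask.mask, fl_img,
                                     bin_width=cfg["curve"]["bin_width_Jcm2"],
                                     exclude_rows=excl_rows)
            per_f0_curves[pair["f0"]].append(curve)
        manifest["mask_pixel_counts"] = mask_px_counts

        stage = "curve"
        avg_curves = {f0: average_curves(cs)
                      for f0, cs in per_f0_curves.items()}
        if out is not None:
            for f0, c in avg_curves.items():
                name = f"curve_F{f0:g}.csv"
                io.save_curve(c, out / name)
                manifest["files"][f"curve_F{f0:g}"] = name
        summary["curves"] = {
            str(f0): {"bin_centers": c.bin_centers.tolist(),
                      "ratio": c.ratio.tolist()}
            for f0, c in avg_curves.items()}

        stage = "fit"
        ranges = tuple(FitRange(f0, *_range_for(cfg, f0))
                       for f0 in cfg["beam"]["fluences_Jcm2"])
        cluster_area = mean_cavity_area_px(spec)
        x, y, n = pool_curves(avg_curves, ranges)
        params, diag = fit_sigmoid(x, y, n_pixels=n,
                                   cluster_area=cluster_area)
        # full-range sensitivity companion fit
        xf, yf, nf = [], [], []
        for f0, c in avg_curves.items():
            keepb = np.isfinite(c.ratio)
            xf.append(c.bin_centers[keepb])
            yf.append(c.ratio[keepb])
            nf.append(c.n_pixels[keepb])
        params_full, diag_full = fit_sigmoid(np.concatenate(xf),
                                             np.concatenate(yf),
                                             n_pixels=np.concatenate(nf),
                                             cluster_area=cluster_area)
        summary["sigmoid_fit"] = {"params": params.as_dict(),
                                  "diagnostics": diag}
        summary["sigmoid_fit_full_range"] = {"params": params_full.as_dict(),
                                             "diagnostics": diag_full}
        if out is not None:
            io.save_sigmoid(params, diag, out / "sigmoid_fit.json")
            manifest["files"]["sigmoid_fit"] = "sigmoid_fit.json"

        stage = "predict"
        maps_abs = []
        pred_seed_base = (seed + 2_000_003) % (2**31 - 1)
        manifest["seeds"]["predict"] = pred_seed_base
        for i, spot in enumerate(cfg["predict"]["spots_mm"]):
            g2 = GridSpec.for_beam(spot,
                                   voxel_size=cfg["grid"]["voxel_size_mm"],
                                   depth=cfg["grid"]["depth_mm"])
            beam = BeamSpec(spot, cfg["predict"]["spot_fluence_Jcm2"])
            fm = simulate_fluence(props, beam, g2,
                                  int(cfg["predict"]["n_photons"]),
                                  (pred_seed_base + i) % (2**31 - 1))
            maps_abs.append(scale_to_absolute(fm, beam))
        for f0 in cfg["beam"]["fluences_Jcm2"]:
            beam = BeamSpec(cfg["beam"]["spot_mm"], f0)
            maps_abs.append(scale_to_absolute(fmap_rel, beam))
        table = depth_tables(maps_abs, params, threshold=params.x0)
        summary["threshold_depths_mm"] = [
            {"spot_mm": m.beam.spot_diameter,
             "fluence_Jcm2": m.beam.irradiation_fluence,
             "depth_mm": threshold_depth(m, params.x0)}
            for m in maps_abs]
        if out is not None:
            table.to_csv(out / "depth_profiles.csv", index=False)
            manifest["files"]["depth_profiles"] = "depth_profiles.csv"
            io.save_json(summary, out / "summary.json")
            io.save_json(manifest, out / "manifest.json")
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(stage, exc, manifest) from exc
    return {"summary": summary, "manifest": manifest}


def _range_for(cfg: dict, f0: float) -> tuple[float, float]:
    for fr in DEFAULT_FIT_RANGES:
        if fr.irradiation_fluence == f0:
            return fr.lo, fr.hi
    # fall back: one 1-J/cm^2-wide band below each non-standard fluence
    return f0 - 1.0, f0
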