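"""File formats: fluence maps as 32-bit float multi-page TIFF with a JSON
sidecar, images/masks as 8-bit TIFF/PNG, curves as CSV, parameters and
manifests as JSON, configs as YAML or JSON."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .dose_response import CavitationCurve, SigmoidParams
from .extraction import CavityMask
from .mc import BeamSpec, FluenceMap, GridSpec
from .synth import PhantomImage


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable config."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def save_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def save_fluence_map(fmap: FluenceMap, path: str | Path) -> None:
    """Multi-page float32 TIFF (one page per depth plane) + JSON sidecar."""
    path = Path(path)
    pages = np.moveaxis(fmap.values.astype(np.float32), 2, 0)  # (nz, nx, ny)
    tifffile.imwrite(path, pages)
    sidecar = {
        "grid": {"nx": fmap.grid.nx, "ny": fmap.grid.ny, "nz": fmap.grid.nz,
                 "voxel_size_mm": fmap.grid.voxel_size},
        "units": fmap.units,
        "photons_launched": fmap.photons_launched,
        "seed": fmap.seed,
        "beam": ({"spot_mm": fmap.beam.spot_diameter,
                  "fluence_Jcm2": fmap.beam.irradiation_fluence}
                 if fmap.beam else None),
        "audit": fmap.audit,
        "page_axis": "depth",
    }
    save_json(sidecar, path.with_suffix(path.suffix + ".json"))


def load_fluence_map(path: str | Path) -> FluenceMap:
    path = Path(path)
    pages = tifffile.imread(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    g = meta["grid"]
    grid = GridSpec(nx=g["nx"], ny=g["ny"], nz=g["nz"],
                    voxel_size=g["voxel_size_mm"])
    values = np.moveaxis(np.asarray(pages, dtype=np.float64), 0, 2)
    beam = None
    if meta.get("beam"):
        beam = BeamSpec(spot_diameter=meta["beam"]["spot_mm"],
                        irradiation_fluence=meta["beam"]["fluence_Jcm2"])
    return FluenceMap(values=values, grid=grid,
                      photons_launched=meta["photons_launched"],
                      seed=meta["seed"], units=meta["units"], beam=beam,
                      audit=meta.get("audit", {}))


def save_axial_slice(slice2d: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), slice2d.astype(np.float32))


def save_image(image: PhantomImage, path: str | Path) -> None:
    iio.imwrite(Path(path), image.pixels)


def load_image(path: str | Path, pixel_size: float, surface_row: int = 0,
               provenance: str = "post") -> PhantomImage:
    pixels = np.asarray(iio.imread(Path(path)))
    if pixels.ndim == 3:
        from .extraction import to_grayscale
        pixels = to_grayscale(pixels)
    return PhantomImage(pixels=pixels.astype(np.uint8),
                        pixel_size=pixel_size, surface_row=surface_row,
                        provenance=provenance, seed=-1)


def save_mask(mask: CavityMask, path: str | Path) -> None:
    iio.imwrite(Path(path), (mask.mask.astype(np.uint8) * 255))


def save_curve(curve: CavitationCurve, path: str | Path) -> None:
    df = pd.DataFrame({
        "bin_lo": curve.bin_edges[:-1],
        "bin_hi": curve.bin_edges[1:],
        "ratio": curve.ratio,
        "n_pixels": curve.n_pixels,
        "sd": curve.sd if curve.sd is not None else np.nan,
    })
    df.to_csv(path, index=False)


def save_sigmoid(params: SigmoidParams, diagnostics: dict,
                 path: str | Path) -> None:
    save_json({"params": params.as_dict(), "diagnostics": diagnostics}, path)
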