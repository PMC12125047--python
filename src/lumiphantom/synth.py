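"""Synthetic phantom cross-section imagery.

Stands in for the wet-lab experiment: pre-irradiation images carry a
Gaussian background texture plus sparse small bright specks (the noise the
extraction stage removes), and post-irradiation images add bright cavity
disks placed by an inhomogeneous Boolean (Poisson-disk) process whose
expected covered-area fraction at a pixel with local fluence x equals the
clamped sigmoid dose-response

    p(x) = clamp( L / (1 + exp(-k (x - x0))) + b, 0, 1 ).

For a Boolean model with center intensity lam (per pixel) and mean stamped
disk area A (pixels), coverage is 1 - exp(-lam * A); the generator therefore
stamps centers at rate lam(x) = -log(1 - p(x)) / A, which makes the expected
covered fraction track the sigmoid exactly (up to disk-scale smoothing of
the fluence field).  Images are 8-bit grayscale; rows are depth (surface at
``surface_row``), columns lateral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dose_response import SigmoidParams

__all__ = [
    "PhantomImage",
    "SynthSpec",
    "generate_pre_image",
    "generate_post_image",
    "generate_experiment",
]


@dataclass
class PhantomImage:
    """8-bit grayscale phantom cross-section raster."""

    pixels: np.ndarray  # uint8, shape (rows=depth, cols=lateral)
    pixel_size: float   # mm
    surface_row: int
    provenance: str     # "pre" | "post"
    seed: int

    def __post_init__(self):
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be uint8")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass(frozen=True)
class SynthSpec:
    """Generator parameters (defaults are the package's study conditions).

    The cavity brightness increment (+40) is far above the +10 segmentation
    rule even when the local mean is inflated by the saturation-plateau
    coverage of ~0.24, so generated cavities satisfy the detection rule by
    construction.  Cavity radii default to 6-20 um (vacuole-scale bubbles
    around pigment organelles); the radius range also sets how many
    independent cavities carry each fluence bin's statistics, and the
    default is sized so the downstream sigmoid fit is limited by those
    counting statistics, not by cavity morphology.
    ``fluence_jitter_fraction`` (off by default) emulates shot-to-shot
    output variation of the laser, e.g. the +/-20% device stability.
    """

    background_level: float = 90.0
    background_noise_sd: float = 3.0
    cavity_radius_range: tuple[float, float] = (0.006, 0.02)  # mm
    cavity_brightness_increment: float = 40.0
    baseline_speck_density: float = 25.0   # per mm^2
    baseline_speck_radius: float = 0.004   # mm
    sigmoid: SigmoidParams = field(
        default_factory=lambda: SigmoidParams(L=0.24, x0=1.37, k=2.0, b=-0.005))
    fluence_jitter_fraction: float = 0.0
    pixel_size: float = 0.01               # mm
    surface_row: int = 0
    surface_artifact_fraction: float = 0.0  # saturated-blob coverage in the top band
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.cavity_radius_range
        if not (0 < lo <= hi):
            raise ValueError("cavity_radius_range must be positive and ordered")
        if self.baseline_speck_radius >= lo:
            raise ValueError("speck radius must be below the minimum cavity radius")
        if self.cavity_brightness_increment < 10:
            raise ValueError("cavity increment must be >= 10 to satisfy the "
                             "detection rule by construction")


def _disk_offsets(radius_mm: float, pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Pixel offsets whose centers lie within radius_mm of a disk center."""
    r_px = radius_mm / pixel_size
    n = int(np.floor(r_px))
    ii, jj = np.meshgrid(np.arange(-n, n + 1), np.arange(-n, n + 1), indexing="ij")
    keep = ii * ii + jj * jj <= r_px * r_px
    return ii[keep], jj[keep]


def _mean_disk_area(radius_range: tuple[float, float], pixel_size: float,
                    n_quad: int = 256) -> float:
    """Expected stamped pixel count for a radius drawn uniformly from the
    range (midpoint quadrature over the continuous uniform)."""
    lo, hi = radius_range
    radii = lo + (np.arange(n_quad) + 0.5) / n_quad * (hi - lo)
    return float(np.mean([_disk_offsets(r, pixel_size)[0].size for r in radii]))


def mean_cavity_area_px(spec: "SynthSpec") -> float:
    """Expected cavity stamp area in pixels for a generator spec — the
    cluster size behind the cavitation-ratio counting statistics."""
    return _mean_disk_area(spec.cavity_radius_range, spec.pixel_size)


def _stamp_disks(covered: np.ndarray, centers_rc: np.ndarray,
                 radii: np.ndarray, pixel_size: float) -> None:
    h, w = covered.shape
    for (r, c), rad in zip(centers_rc, radii):
        di, dj = _disk_offsets(rad, pixel_size)
        ii = di + r
        jj = dj + c
        keep = (ii >= 0) & (ii < h) & (jj >= 0) & (jj < w)
        covered[ii[keep], jj[keep]] = True


def _speck_field(shape: tuple[int, int], spec: SynthSpec,
                 rng: np.random.Generator) -> np.ndarray:
    covered = np.zeros(shape, dtype=bool)
    area_mm2 = shape[0] * shape[1] * spec.pixel_size ** 2
    n = rng.poisson(spec.baseline_speck_density * area_mm2)
    if n:
        rows = rng.integers(0, shape[0], size=n)
        cols = rng.integers(0, shape[1], size=n)
        radii = np.full(n, spec.baseline_speck_radius)
        _stamp_disks(covered, np.column_stack([rows, cols]), radii,
                     spec.pixel_size)
    return covered


def _artifact_band(shape: tuple[int, int], spec: SynthSpec,
                   rng: np.random.Generator) -> np.ndarray:
    """Saturated blobs in the top 0.19-mm band (sectioning artifacts)."""
    sat = np.zeros(shape, dtype=bool)
    if spec.surface_artifact_fraction <= 0:
        return sat
    band = int(np.ceil(0.19 / spec.pixel_size))
    band = min(band, shape[0])
    area_px = band * shape[1]
    blob = _disk_offsets(0.05, spec.pixel_size)
    lam = spec.surface_artifact_fraction * area_px / max(blob[0].size, 1)
    n = rng.poisson(lam)
    if n:
        rows = rng.integers(spec.surface_row, spec.surface_row + band, size=n)
        cols = rng.integers(0, shape[1], size=n)
        _stamp_disks(sat, np.column_stack([rows, cols]),
                     np.full(n, 0.05), spec.pixel_size)
        sat[spec.surface_row + band:, :] = False
    return sat


def _render(spec: SynthSpec, shape, covered: np.ndarray, specks: np.ndarray,
            saturated: np.ndarray, noise_rng: np.random.Generator) -> np.ndarray:
    img = np.full(shape, spec.background_level, dtype=np.float64)
    img[covered | specks] += spec.cavity_brightness_increment
    img += noise_rng.normal(0.0, spec.background_noise_sd, size=shape)
    img[saturated] = 255.0
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_pre_image(spec: SynthSpec, shape: tuple[int, int],
                       seed: int) -> PhantomImage:
    """Pre-irradiation cross-section: textured background plus baseline
    specks. Deterministic under (spec, shape, seed)."""
    children = np.random.SeedSequence(seed).spawn(4)
    noise_rng = np.random.default_rng(children[0])
    speck_rng = np.random.default_rng(children[1])
    art_rng = np.random.default_rng(children[3])
    specks = _speck_field(shape, spec, speck_rng)
    saturated = _artifact_band(shape, spec, art_rng)
    img = _render(spec, shape, np.zeros(shape, dtype=bool), specks,
                  saturated, noise_rng)
    return PhantomImage(pixels=img, pixel_size=spec.pixel_size,
                        surface_row=spec.surface_row, provenance="pre",
                        seed=seed)


def expected_coverage(spec: SynthSpec, fluence: np.ndarray) -> np.ndarray:
    """Clamped sigmoid cavity-coverage probability per pixel."""
    return np.clip(spec.sigmoid(fluence), 0.0, 1.0)


def generate_post_image(spec: SynthSpec, fluence_slice: np.ndarray,
                        seed: int) -> PhantomImage:
    """Post-irradiation cross-section for an absolute fluence slice
    (J/cm^2) already registered to the image grid.

    The pre-image baseline specks (same speck sub-seed) are included; the
    background noise realization differs, as a freshly imaged section would.
    """
    fluence_slice = np.asarray(fluence_slice, dtype=np.float64)
    shape = fluence_slice.shape
    children = np.random.SeedSequence(seed).spawn(4)
    speck_rng = np.random.default_rng(children[1])
    noise_rng = np.random.default_rng(children[2])
    cavity_rng = np.random.default_rng(children[2].spawn(1)[0])
    art_rng = np.random.default_rng(children[3])

    p = np.clip(expected_coverage(spec, fluence_slice), 0.0, 0.999)
    mean_area = _mean_disk_area(spec.cavity_radius_range, spec.pixel_size)
    lam = -np.log1p(-p) / mean_area  # centers per pixel

    # pad so disks whose centers fall just outside still cover edge pixels
    pad = int(np.ceil(spec.cavity_radius_range[1] / spec.pixel_size))
    lam_pad = np.pad(lam, pad, mode="edge")
    counts = cavity_rng.poisson(lam_pad)
    rows, cols = np.nonzero(counts)
    reps = counts[rows, cols]
    rows = np.repeat(rows, reps)
    cols = np.repeat(cols, reps)
    covered_pad = np.zeros(lam_pad.shape, dtype=bool)
    if rows.size:
        radii = cavity_rng.uniform(*spec.cavity_radius_range, size=rows.size)
        _stamp_disks(covered_pad, np.column_stack([rows, cols]), radii,
                     spec.pixel_size)
    covered = covered_pad[pad:pad + shape[0], pad:pad + shape[1]]

    specks = _speck_field(shape, spec, speck_rng)
    saturated = _artifact_band(shape, spec, art_rng)
    img = _render(spec, shape, covered, specks, saturated, noise_rng)
    return PhantomImage(pixels=img, pixel_size=spec.pixel_size,
                        surface_row=spec.surface_row, provenance="post",
                        seed=seed)


def generate_experiment(spec: SynthSpec, fluence_slices: dict[float, np.ndarray],
                        n_replicates: int, seed: int) -> dict:
    """Replicated pre/post pairs for each irradiation fluence.

    Parameters
    ----------
    fluence_slices : dict
        Maps irradiation fluence F0 (J/cm^2) to the absolute fluence slice
        on the image grid for that F0.
    n_replicates : int
        Independent pre/post pairs per fluence (the study irradiated five
        locations per condition).

    Returns a manifest dict with the generated pairs and, per shot, the
    sub-seed and the realized fluence jitter multiplier — enough to
    regenerate every image bit-identically.
    """
    master = np.random.SeedSequence(seed)
    jitter_rng = np.random.default_rng(master.spawn(1)[0])
    pairs = []
    pair_seed = int(np.random.default_rng(master).integers(0, 2**31 - 1))
    counter = 0
    for f0 in sorted(fluence_slices):
        for rep in range(n_replicates):
            shot_seed = (pair_seed + 7919 * counter) % (2**31 - 1)
            counter += 1
            j = spec.fluence_jitter_fraction
            mult = float(jitter_rng.uniform(1 - j, 1 + j)) if j > 0 else 1.0
            pre = generate_pre_image(spec, fluence_slices[f0].shape, shot_seed)
            post = generate_post_image(spec, fluence_slices[f0] * mult,
                                       shot_seed)
            pairs.append({"f0": f0, "replicate": rep, "seed": shot_seed,
                          "fluence_multiplier": mult, "pre": pre,
                          "post": post})
    manifest = {
        "seed": seed,
        "n_replicates": n_replicates,
        "fluences": sorted(fluence_slices),
        "sigmoid": {"L": spec.sigmoid.L, "x0": spec.sigmoid.x0,
                    "k": spec.sigmoid.k, "b": spec.sigmoid.b},
        "shots": [{k: p[k] for k in ("f0", "replicate", "seed",
                                     "fluence_multiplier")} for p in pairs],
    }
    return {"pairs": pairs, "manifest": manifest}
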