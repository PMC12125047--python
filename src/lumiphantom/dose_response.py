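"""Fluence-binned cavitation dose-response and sigmoid threshold fitting.

The cavitation ratio is the fraction of cavity pixels among all pixels
whose local (in-phantom, absolute) fluence falls in a 0.1-J/cm^2 bin. The
ratio-vs-fluence curve is fitted with the four-parameter logistic

    y = L / (1 + exp(-k (x - x0))) + b

whose inflection x0 is the cavitation-onset threshold fluence. Curves from
different irradiation fluences are pooled over assigned in-phantom fluence
intervals before fitting (low-fluence bins of high-F0 shots are noisy far
off axis, so each irradiation fluence contributes only its assigned range).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import curve_fit

__all__ = [
    "SigmoidParams",
    "CavitationCurve",
    "FitRange",
    "DEFAULT_FIT_RANGES",
    "sigmoid",
    "resample_axial_slice",
    "align_by_centroid",
    "cavitation_curve",
    "average_curves",
    "pool_curves",
    "fit_sigmoid",
]


def sigmoid(x, L, x0, k, b):
    """Four-parameter logistic dose-response."""
    return L / (1.0 + np.exp(-k * (np.asarray(x, dtype=float) - x0))) + b


@dataclass(frozen=True)
class SigmoidParams:
    """(L, x0, k, b): saturation ratio, threshold fluence (J/cm^2),
    slope ((J/cm^2)^-1), baseline offset."""

    L: float
    x0: float
    k: float
    b: float

    def __call__(self, x):
        return sigmoid(x, self.L, self.x0, self.k, self.b)

    def as_dict(self) -> dict:
        return {"L": self.L, "x0": self.x0, "k": self.k, "b": self.b}


@dataclass(frozen=True)
class FitRange:
    """In-phantom fluence interval [lo, hi) assigned to one irradiation
    fluence when pooling curves for the sigmoid fit."""

    irradiation_fluence: float
    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError("fit range must satisfy lo < hi")


#: Per-irradiation-fluence in-phantom intervals used for the pooled fit.
DEFAULT_FIT_RANGES = (
    FitRange(2.0, 0.0, 2.0),
    FitRange(3.0, 2.0, 3.0),
    FitRange(4.0, 3.0, 4.0),
    FitRange(5.0, 4.0, 5.0),
)


@dataclass
class CavitationCurve:
    """Cavitation ratio per uniform fluence bin.

    ``ratio`` is NaN where a bin holds no pixels (never 0/0); ``sd`` is the
    across-replicate standard deviation when the curve is an average.
    """

    bin_edges: np.ndarray  # len B+1, J/cm^2
    ratio: np.ndarray      # len B, NaN for empty bins
    n_pixels: np.ndarray   # len B
    sd: np.ndarray | None = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def resample_axial_slice(fluence_slice: np.ndarray, voxel_size: float,
                         shape: tuple[int, int], pixel_size: float,
                         surface_row: int = 0,
                         axis_col: float | None = None) -> np.ndarray:
    """Bilinearly resample an axial fluence slice (n_lateral, n_depth) onto
    an image grid (rows = depth, cols = lateral) with the beam axis placed
    at image column ``axis_col`` (default: geometric center). Pixels above
    the surface row are set to 0."""
    h, w = shape
    if axis_col is None:
        axis_col = (w - 1) / 2.0
    axis_ix = fluence_slice.shape[0] // 2
    rows = np.arange(h)
    cols = np.arange(w)
    depth_mm = (rows - surface_row + 0.5) * pixel_size
    lateral_mm = (cols - axis_col) * pixel_size
    ix = lateral_mm / voxel_size + axis_ix
    iz = depth_mm / voxel_size - 0.5
    II, ZZ = np.meshgrid(ix, iz, indexing="xy")
    out = map_coordinates(fluence_slice, [II.ravel(), ZZ.ravel()],
                          order=1, mode="nearest").reshape(h, w)
    out[rows < surface_row, :] = 0.0
    return out


def align_by_centroid(mask, fluence_slice: np.ndarray, voxel_size: float,
                      surface_row: int | None = None):
    """Resample an axial fluence slice onto a cavity mask's pixel grid,
    laterally shifted so the simulated beam axis sits on the lateral
    centroid of the mask pixels.

    Parameters
    ----------
    mask : CavityMask
        Segmented cavities (rows = depth, cols = lateral), carries
        ``pixel_size`` and ``surface_row``.
    fluence_slice : ndarray, shape (n_lateral, n_depth)
        Axial plane of the fluence map; the beam axis is the central
        lateral index. Values may be relative or absolute; they are
        interpolated bilinearly (masks are never interpolated).
    voxel_size : float
        Fluence voxel size, mm.

    Returns
    -------
    fluence_img : ndarray
        Fluence on the image grid (same shape as the mask). Pixels above
        the surface row get 0.
    shift_mm : float
        Applied lateral shift of the fluence axis relative to the image
        center (negative when the mask centroid sits left of center).
    """
    import warnings

    ps = mask.pixel_size
    surface = mask.surface_row if surface_row is None else surface_row
    h, w = mask.mask.shape
    if mask.mask.any():
        centroid_col = float(np.mean(np.nonzero(mask.mask)[1]))
    else:
        warnings.warn("empty mask: falling back to the geometric image "
                      "center for alignment", stacklevel=2)
        centroid_col = (w - 1) / 2.0
    fluence_img = resample_axial_slice(fluence_slice, voxel_size, (h, w), ps,
                                       surface_row=surface,
                                       axis_col=centroid_col)
    shift_mm = (centroid_col - (w - 1) / 2.0) * ps
    return fluence_img, shift_mm


def cavitation_curve(mask: np.ndarray, fluence_img: np.ndarray,
                     bin_width: float = 0.1,
                     exclude_rows: int = 0) -> CavitationCurve:
    """Bin pixels by their absolute fluence and compute per-bin cavity
    fractions.

    ``mask`` and ``fluence_img`` must be congruent; the first
    ``exclude_rows`` image rows (the surface band) are dropped from both
    numerator and denominator.
    """
    m = np.asarray(mask, dtype=bool)[exclude_rows:, :].ravel()
    f = np.asarray(fluence_img, dtype=float)[exclude_rows:, :].ravel()
    if m.shape != f.shape:
        raise ValueError("mask and fluence image must be congruent")
    n_bins = max(int(np.ceil((f.max() + 1e-12) / bin_width)), 1)
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.minimum((f / bin_width).astype(np.intp), n_bins - 1)
    n_pixels = np.bincount(idx, minlength=n_bins)
    n_cavity = np.bincount(idx[m], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        ratio = np.where(n_pixels > 0, n_cavity / np.maximum(n_pixels, 1),
                         np.nan)
    ratio[n_pixels == 0] = np.nan
    return CavitationCurve(bin_edges=edges, ratio=ratio, n_pixels=n_pixels)


def average_curves(curves: list[CavitationCurve]) -> CavitationCurve:
    """Per-bin mean (and sd) across replicate curves; bins are aligned by
    edge value, shorter curves padded with NaN."""
    if not curves:
        raise ValueError("no curves to average")
    bw = curves[0].bin_edges[1] - curves[0].bin_edges[0]
    n = max(c.ratio.size for c in curves)
    stack = np.full((len(curves), n), np.nan)
    npx = np.zeros((len(curves), n), dtype=np.int64)
    for i, c in enumerate(curves):
        if abs(c.bin_edges[1] - c.bin_edges[0] - bw) > 1e-12:
            raise ValueError("curves must share a bin width")
        stack[i, :c.ratio.size] = c.ratio
        npx[i, :c.ratio.size] = c.n_pixels
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    edges = np.arange(n + 1) * bw
    return CavitationCurve(bin_edges=edges, ratio=mean,
                           n_pixels=npx.sum(axis=0), sd=sd)


def pool_curves(curves: dict[float, CavitationCurve],
                fit_ranges=DEFAULT_FIT_RANGES) -> tuple[np.ndarray, np.ndarray]:
    """Pool per-fluence curves into one (x, y) fit set.

    Each irradiation fluence contributes only the bins whose centers fall
    inside its assigned [lo, hi) interval. Overlapping intervals are an
    error. Returns sorted bin centers, ratios and per-bin pixel counts
    (NaN bins dropped).
    """
    ranges = {fr.irradiation_fluence: fr for fr in fit_ranges}
    ivals = sorted((fr.lo, fr.hi) for fr in fit_ranges)
    for (lo1, hi1), (lo2, hi2) in zip(ivals, ivals[1:]):
        if lo2 < hi1:
            raise ValueError("fit ranges overlap")
    xs, ys, ns = [], [], []
    for f0, curve in curves.items():
        if f0 not in ranges:
            raise KeyError(f"no fit range assigned to irradiation fluence {f0}")
        fr = ranges[f0]
        centers = curve.bin_centers
        keep = (centers >= fr.lo) & (centers < fr.hi) & np.isfinite(curve.ratio)
        xs.append(centers[keep])
        ys.append(curve.ratio[keep])
        ns.append(np.asarray(curve.n_pixels)[keep])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    n = np.concatenate(ns)
    order = np.argsort(x)
    return x[order], y[order], n[order]


def fit_sigmoid(x: np.ndarray, y: np.ndarray, n_pixels=None,
                cluster_area: float = 1.0,
                min_points: int = 8) -> tuple[SigmoidParams, dict]:
    """Least-squares fit of the four-parameter logistic.

    Without ``n_pixels`` the fit is unweighted. With ``n_pixels`` (per-bin
    pixel counts) each bin is weighted by the inverse of its cluster-
    binomial variance  p(1-p) * cluster_area / n  — where ``cluster_area``
    is the mean cavity area in pixels, so n / cluster_area counts the
    independent cavities behind the bin — iterating the weights from the
    fitted curve twice (IRLS). Sparse bins otherwise dominate the fit
    noise, since a fluence bin holding a handful of cavities carries far
    less information than one holding thousands.

    Initialization: L0 = max - min, b0 = min, x00 = abscissa of the
    half-rise, k0 = 4 / central-rise span; L and k are bounded positive.
    Returns the parameters plus diagnostics (rss, converged flag, and the
    reasons when flagged). Degenerate (constant) data are flagged with k
    unidentifiable and the input mean returned as b.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    if n_pixels is not None:
        n_pixels = np.asarray(n_pixels, dtype=float)[keep]
    x, y = x[keep], y[keep]
    diagnostics: dict = {"n_points": int(x.size), "flags": []}
    if x.size < min_points:
        diagnostics["flags"].append("too_few_points")
    span = float(np.ptp(y)) if y.size else 0.0
    if y.size == 0 or span < 1e-12:
        diagnostics["flags"].append("degenerate_constant_data")
        diagnostics["converged"] = False
        diagnostics["rss"] = 0.0
        params = SigmoidParams(L=0.0, x0=float(np.mean(x)) if x.size else 0.0,
                               k=np.nan, b=float(np.mean(y)) if y.size else 0.0)
        return params, diagnostics

    y_lo, y_hi = float(np.min(y)), float(np.max(y))
    half = 0.5 * (y_lo + y_hi)
    above = x[y >= half]
    x00 = float(above.min()) if above.size else float(np.median(x))
    rise_lo = x[y <= y_lo + 0.25 * span]
    rise_hi = x[y >= y_lo + 0.75 * span]
    span_x = (float(rise_hi.min()) - float(rise_lo.max())
              if rise_lo.size and rise_hi.size else 0.0)
    k0 = 4.0 / span_x if span_x > 1e-9 else 4.0 / max(np.ptp(x), 1e-9)
    k0 = float(np.clip(k0, 1e-3, 1e3))
    p0 = [span, x00, k0, y_lo]
    bounds = ([1e-9, -np.inf, 1e-9, -np.inf],
              [np.inf, np.inf, np.inf, np.inf])
    converged = True
    try:
        if n_pixels is None:
            popt, _ = curve_fit(sigmoid, x, y, p0=p0, bounds=bounds,
                                maxfev=20000)
        else:
            popt = p0
            for it in range(3):
                p_hat = np.clip(sigmoid(x, *popt) if it else y, 0.005, 0.995)
                sig = np.sqrt(p_hat * (1.0 - p_hat) * cluster_area
                              / np.maximum(n_pixels, cluster_area))
                popt, _ = curve_fit(sigmoid, x, y, p0=popt, sigma=sig,
                                    bounds=bounds, maxfev=20000)
    except RuntimeError:
        popt = p0
        converged = False
        diagnostics["flags"].append("did_not_converge")
    params = SigmoidParams(L=float(popt[0]), x0=float(popt[1]),
                           k=float(popt[2]), b=float(popt[3]))
    if not (x.min() <= params.x0 <= x.max()):
        diagnostics["flags"].append("x0_outside_data_range")
        converged = False
    resid = y - params(x)
    diagnostics["rss"] = float(resid @ resid)
    diagnostics["converged"] = converged
    return params, diagnostics
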