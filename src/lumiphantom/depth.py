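"""Cavitation-depth prediction from absolute fluence maps.

Composes the on-axis fluence profile with the fitted sigmoid dose-response
to predict how deep cavitation extends for a given irradiation fluence and
spot size: the threshold depth is the deepest point where the absolute
on-axis fluence still reaches the cavitation-onset threshold, and the
ratio-vs-depth profile is the clamped sigmoid of the on-axis fluence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_response import SigmoidParams
from .mc import FluenceMap

__all__ = ["DepthProfile", "on_axis_fluence", "threshold_depth",
           "ratio_vs_depth", "depth_tables"]

#: Returned when the threshold fluence is never reached on the axis.
NOT_REACHED = float("nan")


@dataclass
class DepthProfile:
    """On-axis depth grid (mm), absolute fluence (J/cm^2) and predicted
    cavitation ratio (clamped to [0, 1])."""

    depth: np.ndarray
    fluence: np.ndarray
    ratio: np.ndarray
    spot_diameter: float | None = None
    irradiation_fluence: float | None = None


def on_axis_fluence(fmap: FluenceMap) -> tuple[np.ndarray, np.ndarray]:
    """Depth grid and on-axis fluence, averaged over the 3x3 voxel column
    around the beam axis to suppress Monte Carlo noise."""
    g = fmap.grid
    cx, cy = g.nx // 2, g.ny // 2
    sl = fmap.values[max(cx - 1, 0):cx + 2, max(cy - 1, 0):cy + 2, :]
    return g.depths, sl.mean(axis=(0, 1))


def threshold_depth(fmap: FluenceMap, threshold: float) -> float:
    """Deepest on-axis depth (mm) where absolute fluence >= threshold,
    linearly interpolated between the bracketing voxel centers; NaN when
    the threshold is never reached.

    The deepest crossing (not the first) is used because backscatter makes
    the near-surface profile non-monotone.
    """
    if fmap.is_relative:
        raise ValueError("threshold_depth needs an absolute fluence map")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    z, f = on_axis_fluence(fmap)
    above = np.flatnonzero(f >= threshold)
    if above.size == 0:
        return NOT_REACHED
    i = above[-1]
    if i == f.size - 1:
        return float(z[i])
    # interpolate between the last voxel at/above threshold and the next
    z0, z1 = z[i], z[i + 1]
    f0, f1 = f[i], f[i + 1]
    if f1 >= threshold or f0 == f1:
        return float(z0)
    return float(z0 + (f0 - threshold) / (f0 - f1) * (z1 - z0))


def ratio_vs_depth(fmap: FluenceMap, params: SigmoidParams) -> DepthProfile:
    """Predicted cavitation ratio along the axis: clamp(sigmoid(F(z)), 0, 1)."""
    if fmap.is_relative:
        raise ValueError("ratio_vs_depth needs an absolute fluence map")
    z, f = on_axis_fluence(fmap)
    ratio = np.clip(params(f), 0.0, 1.0)
    beam = fmap.beam
    return DepthProfile(depth=z, fluence=f, ratio=ratio,
                        spot_diameter=beam.spot_diameter if beam else None,
                        irradiation_fluence=(beam.irradiation_fluence
                                             if beam else None))


def depth_tables(maps: list[FluenceMap], params: SigmoidParams,
                 threshold: float) -> pd.DataFrame:
    """Tabulated ratio-vs-depth profiles for a set of absolute maps
    (one row per depth sample per configuration), with each
    configuration's threshold depth attached."""
    frames = []
    for fmap in maps:
        prof = ratio_vs_depth(fmap, params)
        td = threshold_depth(fmap, threshold)
        frames.append(pd.DataFrame({
            "spot_mm": prof.spot_diameter,
            "fluence_Jcm2": prof.irradiation_fluence,
            "depth_mm": prof.depth,
            "onaxis_fluence_Jcm2": prof.fluence,
            "cavitation_ratio": prof.ratio,
            "threshold_depth_mm": td,
        }))
    return pd.concat(frames, ignore_index=True)
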