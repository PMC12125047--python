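"""Inverse Monte Carlo estimation of (mua, mus) from slab R/T.

Emulates the double-integrating-sphere characterization of the phantom as a
bare 1-mm slab: the forward model is :func:`lumiphantom.mc.simulate_slab_RT`
and the inverse problem is a derivative-free minimization of the squared
relative misfit of (R_total, T_total) over (log mua, log mus), with the
anisotropy g and refractive index n held fixed.

Common random numbers: every objective evaluation reuses the same MC seed,
so the objective is a deterministic, quasi-smooth function of (mua, mus)
and Nelder-Mead can terminate on small simplex sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .mc import OpticalProperties, SlabMeasurement, simulate_slab_RT

__all__ = ["InversionResult", "invert_optical_properties"]


@dataclass
class InversionResult:
    props: OpticalProperties
    residual: float
    iterations: int
    converged: bool


def _initial_guess(measured: SlabMeasurement, g: float) -> tuple[float, float]:
    """Crude starting point: Beer-type attenuation for mua, diffuse
    reflectance level for mus."""
    T = max(measured.T_total, 1e-6)
    mua0 = max(0.5 * (-np.log(T)) / measured.thickness, 1e-2)
    # diffuse (non-specular) reflectance grows with scattering
    r_diff = max(measured.R_total - 0.03, 1e-3)
    mus_prime0 = np.clip(20.0 * r_diff, 0.3, 10.0)
    return mua0, mus_prime0 / (1.0 - g)


def invert_optical_properties(measured: SlabMeasurement, g: float, n: float,
                              thickness: float | None = None,
                              mc_budget: int = 100_000, seed: int = 0,
                              max_iter: int = 200,
                              tol: float = 1e-3) -> InversionResult:
    """Recover (mua, mus) from a slab measurement with fixed (g, n).

    Parameters
    ----------
    measured : SlabMeasurement
        Total reflectance and transmittance (specular included) of the slab.
    g, n : float
        Anisotropy and refractive index assumed for the inversion.
    thickness : float, optional
        Slab thickness, mm; defaults to ``measured.thickness``.
    mc_budget : int
        Photons per objective evaluation (>= 1e4 recommended).
    seed : int
        Master seed; every forward evaluation reuses it (common random
        numbers) so the objective is deterministic in (mua, mus).
    """
    if thickness is None:
        thickness = measured.thickness
    R_m, T_m = measured.R_total, measured.T_total
    if not (0.0 < R_m + T_m <= 1.0 + 1e-9):
        raise ValueError("measurement outside the physical range "
                         "0 < R + T <= 1")

    def make_objective(budget: int):
        def objective(logp: np.ndarray) -> float:
            mua = float(np.exp(logp[0]))
            mus = float(np.exp(logp[1]))
            sim = simulate_slab_RT(
                OpticalProperties(mua=mua, mus=mus, g=g, n=n),
                thickness, budget, seed)
            rr = (sim.R_total - R_m) / max(R_m, 1e-3)
            tt = (sim.T_total - T_m) / max(T_m, 1e-3)
            return rr * rr + tt * tt
        return objective

    objective = make_objective(mc_budget)
    coarse_objective = make_objective(max(mc_budget // 4, 10_000))

    mua0, mus0 = _initial_guess(measured, g)
    x0 = np.log([mua0, mus0])

    # Stage 1: coarse log-space grid around the heuristic start. The MC
    # objective has broad curvature in log space, so a factor-of-~6 bracket
    # reliably contains the optimum even for a poor heuristic.
    offsets = np.linspace(-1.8, 1.8, 5)
    best = x0.copy()
    best_f = np.inf
    for da in offsets:
        for ds in offsets:
            p = x0 + np.array([da, ds])
            f = coarse_objective(p)
            if f < best_f:
                best_f = f
                best = p

    # Stage 2: Nelder-Mead from the best grid node with a generous simplex
    # (edges ~0.45 in log space, i.e. ~55% parameter steps) so MC noise
    # cannot collapse it prematurely.
    simplex = np.array([best, best + [0.45, 0.0], best + [0.0, 0.45]])
    res = minimize(objective, best, method="Nelder-Mead",
                   options={"maxiter": max_iter, "xatol": 1e-2,
                            "fatol": tol ** 2, "initial_simplex": simplex})
    mua, mus = np.exp(res.x)
    props = OpticalProperties(mua=float(mua), mus=float(mus), g=g, n=n)
    # residual consistent with the MC noise floor counts as converged
    s_r2 = R_m * (1.0 - R_m) / mc_budget
    s_t2 = T_m * (1.0 - T_m) / mc_budget
    noise_floor = 16.0 * (s_r2 / max(R_m, 1e-3) ** 2 +
                          s_t2 / max(T_m, 1e-3) ** 2)
    converged = bool(res.fun <= max(noise_floor, tol ** 2))
    return InversionResult(props=props, residual=float(res.fun),
                           iterations=int(res.nit), converged=converged)
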