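"""Numba photon-transport kernels.

Hop-drop-spin random walk in a homogeneous medium with a Henyey-Greenstein
phase function, MCML-style weight deposition (dw = w*mua/mut per interaction)
and a track-length (pathlength) fluence tally.  Single-threaded so that a
fixed seed gives bit-identical tallies.

Audit array layout (weights, summed over all launched photons):
  0 specular reflection at entry
  1 absorbed in the medium
  2 escaped through the top (illuminated) face, specular excluded
  3 escaped through the bottom face
  4 escaped laterally
  5 weight destroyed by Russian roulette
  6 weight created by roulette survival boosting
"""

import math

import numpy as np
from numba import njit

AUDIT_SPECULAR = 0
AUDIT_ABSORBED = 1
AUDIT_TOP = 2
AUDIT_BOTTOM = 3
AUDIT_LATERAL = 4
AUDIT_ROULETTE_KILLED = 5
AUDIT_ROULETTE_CREATED = 6

W_ROULETTE = 1e-4
ROULETTE_SURVIVAL = 10.0


@njit(cache=True)
def _fresnel_unpolarized(n1, n2, cos_i):
    """Unpolarized Fresnel reflectance for incidence cosine cos_i (>0)."""
    if n1 == n2:
        return 0.0
    if cos_i > 0.999999:
        r = (n1 - n2) / (n1 + n2)
        return r * r
    sin_i = math.sqrt(max(0.0, 1.0 - cos_i * cos_i))
    sin_t = n1 / n2 * sin_i
    if sin_t >= 1.0:
        return 1.0  # total internal reflection
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _hg_cos(g):
    """Sample the cosine of the HG deflection angle."""
    if g == 0.0:
        return 2.0 * np.random.random() - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
    c = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True)
def _spin(ux, uy, uz, g):
    """New direction after an HG scattering event."""
    cost = _hg_cos(g)
    sint = math.sqrt(max(0.0, 1.0 - cost * cost))
    phi = 2.0 * math.pi * np.random.random()
    cosp = math.cos(phi)
    sinp = math.sin(phi)
    if abs(uz) > 0.99999:
        nux = sint * cosp
        nuy = sint * sinp
        nuz = cost if uz > 0.0 else -cost
    else:
        denom = math.sqrt(1.0 - uz * uz)
        nux = sint * (ux * uz * cosp - uy * sinp) / denom + ux * cost
        nuy = sint * (uy * uz * cosp + ux * sinp) / denom + uy * cost
        nuz = -denom * sint * cosp + uz * cost
    norm = math.sqrt(nux * nux + nuy * nuy + nuz * nuz)
    return nux / norm, nuy / norm, nuz / norm


@njit(cache=True)
def _tally_segment(tally, x, y, z, ux, uy, uz, seg, w, nx, ny, nz, ds, xmin, ymin):
    """Add w * pathlength to every voxel crossed by a segment fully inside
    the domain (Amanatides-Woo voxel walk: one face crossing per iteration,
    so the cost is bounded by ~3 * seg / ds)."""
    big = 1e30
    ix = int((x - xmin) / ds)
    iy = int((y - ymin) / ds)
    iz = int(z / ds)
    if ix < 0:
        ix = 0
    elif ix >= nx:
        ix = nx - 1
    if iy < 0:
        iy = 0
    elif iy >= ny:
        iy = ny - 1
    if iz < 0:
        iz = 0
    elif iz >= nz:
        iz = nz - 1
    if ux > 0.0:
        step_x = 1
        t_max_x = (xmin + (ix + 1) * ds - x) / ux
        t_dx = ds / ux
    elif ux < 0.0:
        step_x = -1
        t_max_x = (xmin + ix * ds - x) / ux
        t_dx = -ds / ux
    else:
        step_x = 0
        t_max_x = big
        t_dx = big
    if uy > 0.0:
        step_y = 1
        t_max_y = (ymin + (iy + 1) * ds - y) / uy
        t_dy = ds / uy
    elif uy < 0.0:
        step_y = -1
        t_max_y = (ymin + iy * ds - y) / uy
        t_dy = -ds / uy
    else:
        step_y = 0
        t_max_y = big
        t_dy = big
    if uz > 0.0:
        step_z = 1
        t_max_z = ((iz + 1) * ds - z) / uz
        t_dz = ds / uz
    elif uz < 0.0:
        step_z = -1
        t_max_z = (iz * ds - z) / uz
        t_dz = -ds / uz
    else:
        step_z = 0
        t_max_z = big
        t_dz = big
    t_cur = 0.0
    while True:
        t_next = seg
        axis = -1
        if t_max_x < t_next:
            t_next = t_max_x
            axis = 0
        if t_max_y < t_next:
            t_next = t_max_y
            axis = 1
        if t_max_z < t_next:
            t_next = t_max_z
            axis = 2
        if t_next > t_cur:
            tally[ix, iy, iz] += w * (t_next - t_cur)
        if axis == -1:
            break
        if axis == 0:
            ix += step_x
            t_max_x += t_dx
            if ix < 0:
                ix = 0
            elif ix >= nx:
                ix = nx - 1
        elif axis == 1:
            iy += step_y
            t_max_y += t_dy
            if iy < 0:
                iy = 0
            elif iy >= ny:
                iy = ny - 1
        else:
            iz += step_z
            t_max_z += t_dz
            if iz < 0:
                iz = 0
            elif iz >= nz:
                iz = nz - 1
        t_cur = t_next
    return x + ux * seg, y + uy * seg, z + uz * seg


@njit(cache=True)
def run_fluence(n_photons, seed, mua, mus, g, n_med, beam_radius,
                nx, ny, nz, ds, tally, audit):
    """Top-hat beam, normal incidence at z=0; fluence tallied as track length.

    Boundaries: top face air/medium Fresnel (specular entry loss deducted),
    bottom face totally absorbing, lateral faces absorbing.
    """
    np.random.seed(seed)
    mut = mua + mus
    xmin = -0.5 * nx * ds
    ymin = -0.5 * ny * ds
    xmax = -xmin
    ymax = -ymin
    zmax = nz * ds
    rsp = 0.0
    if n_med != 1.0:
        r = (n_med - 1.0) / (n_med + 1.0)
        rsp = r * r
    big = 1e12
    for _ in range(n_photons):
        # launch uniformly over the beam disk
        while True:
            px = (2.0 * np.random.random() - 1.0) * beam_radius
            py = (2.0 * np.random.random() - 1.0) * beam_radius
            if px * px + py * py <= beam_radius * beam_radius:
                break
        x = px
        y = py
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        audit[AUDIT_SPECULAR] += rsp
        w = 1.0 - rsp
        alive = True
        while alive:
            if mut > 0.0:
                s = -math.log(np.random.random()) / mut
            else:
                s = big
            while s > 0.0 and alive:
                # distance to the nearest domain face along the direction
                tb = big
                face = -1
                if ux > 0.0:
                    t = (xmax - x) / ux
                    if t < tb:
                        tb = t
                        face = 4
                elif ux < 0.0:
                    t = (xmin - x) / ux
                    if t < tb:
                        tb = t
                        face = 4
                if uy > 0.0:
                    t = (ymax - y) / uy
                    if t < tb:
                        tb = t
                        face = 4
                elif uy < 0.0:
                    t = (ymin - y) / uy
                    if t < tb:
                        tb = t
                        face = 4
                if uz > 0.0:
                    t = (zmax - z) / uz
                    if t < tb:
                        tb = t
                        face = 3
                elif uz < 0.0:
                    t = (0.0 - z) / uz
                    if t < tb:
                        tb = t
                        face = 2
                if tb < 0.0:
                    tb = 0.0
                if s < tb:
                    x, y, z = _tally_segment(tally, x, y, z, ux, uy, uz, s, w,
                                             nx, ny, nz, ds, xmin, ymin)
                    s = 0.0
                else:
                    x, y, z = _tally_segment(tally, x, y, z, ux, uy, uz, tb, w,
                                             nx, ny, nz, ds, xmin, ymin)
                    s -= tb
                    if face == 2:
                        z = 0.0
                        cos_i = -uz
                        if np.random.random() < _fresnel_unpolarized(n_med, 1.0, cos_i):
                            uz = -uz
                        else:
                            audit[AUDIT_TOP] += w
                            alive = False
                    elif face == 3:
                        audit[AUDIT_BOTTOM] += w
                        alive = False
                    else:
                        audit[AUDIT_LATERAL] += w
                        alive = False
            if not alive or mut <= 0.0:
                break
            # interaction: deposit, roulette, scatter
            if mua > 0.0:
                dw = w * mua / mut
                audit[AUDIT_ABSORBED] += dw
                w -= dw
            if w <= 0.0:
                break
            if w < W_ROULETTE:
                if np.random.random() < 1.0 / ROULETTE_SURVIVAL:
                    audit[AUDIT_ROULETTE_CREATED] += w * (ROULETTE_SURVIVAL - 1.0)
                    w *= ROULETTE_SURVIVAL
                else:
                    audit[AUDIT_ROULETTE_KILLED] += w
                    alive = False
                    break
            ux, uy, uz = _spin(ux, uy, uz, g)


@njit(cache=True)
def run_slab(n_photons, seed, mua, mus, g, n_med, thickness):
    """Laterally unbounded slab in air; returns (R_total, T_total, A_total).

    R_total includes the specular entry reflection; both faces are
    Fresnel interfaces between the medium and air (none when n_med == 1).
    """
    np.random.seed(seed)
    mut = mua + mus
    rsp = 0.0
    if n_med != 1.0:
        r = (n_med - 1.0) / (n_med + 1.0)
        rsp = r * r
    R = rsp * n_photons
    T = 0.0
    A = 0.0
    big = 1e12
    for _ in range(n_photons):
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0 - rsp
        alive = True
        while alive:
            if mut > 0.0:
                s = -math.log(np.random.random()) / mut
            else:
                s = big
            while s > 0.0 and alive:
                if uz > 0.0:
                    tb = (thickness - z) / uz
                    top = False
                elif uz < 0.0:
                    tb = -z / uz
                    top = True
                else:
                    tb = big
                    top = False
                if s < tb:
                    z += uz * s
                    s = 0.0
                else:
                    s -= tb
                    if top:
                        z = 0.0
                        if np.random.random() < _fresnel_unpolarized(n_med, 1.0, -uz):
                            uz = -uz
                        else:
                            R += w
                            alive = False
                    else:
                        z = thickness
                        if np.random.random() < _fresnel_unpolarized(n_med, 1.0, uz):
                            uz = -uz
                        else:
                            T += w
                            alive = False
            if not alive or mut <= 0.0:
                break
            if mua > 0.0:
                dw = w * mua / mut
                A += dw
                w -= dw
            if w <= 0.0:
                break
            if w < W_ROULETTE:
                if np.random.random() < 1.0 / ROULETTE_SURVIVAL:
                    w *= ROULETTE_SURVIVAL
                else:
                    alive = False
                    break
            ux, uy, uz = _spin(ux, uy, uz, g)
    return R / n_photons, T / n_photons, A / n_photons
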