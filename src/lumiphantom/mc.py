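"""Voxelized Monte Carlo photon transport in a homogeneous turbid phantom.

Models a melanosome/Intralipid gelatin phantom illuminated by a normally
incident circular top-hat beam and tallies the relative fluence
(local fluence / incident surface fluence) on a voxel grid, plus total
reflectance/transmittance of a bare slab for optical-property work.

Conventions
-----------
* Depth ``z`` is 0 at the illuminated surface and increases into the medium.
* The beam axis is the lateral center of the grid; lateral voxel counts are
  kept odd so a single center voxel column lies on the axis.
* The top face is an air/medium Fresnel interface (specular entry reflection
  is deducted from the launched weight); the bottom face is totally
  absorbing, emulating black foil beneath the phantom; lateral faces absorb
  and the escaped weight is reported in the audit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels

__all__ = [
    "OpticalProperties",
    "BeamSpec",
    "GridSpec",
    "FluenceMap",
    "SlabMeasurement",
    "simulate_fluence",
    "simulate_slab_RT",
    "scale_to_absolute",
    "extract_axial_slice",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of the medium.

    Parameters
    ----------
    mua : float
        Absorption coefficient, mm^-1.
    mus : float
        Scattering coefficient, mm^-1.
    g : float
        Scattering anisotropy (mean cosine of the HG deflection), in [0, 1).
    n : float
        Refractive index (>= 1); ambient is air, n = 1.
    """

    mua: float
    mus: float
    g: float
    n: float

    def __post_init__(self):
        if self.mua < 0 or self.mus < 0:
            raise ValueError("mua and mus must be non-negative")
        if not (0 <= self.g < 1):
            raise ValueError("g must satisfy 0 <= g < 1")
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")

    @property
    def mus_prime(self) -> float:
        """Reduced scattering coefficient mus * (1 - g), mm^-1."""
        return self.mus * (1.0 - self.g)

    @classmethod
    def from_reduced(cls, mua: float, mus_prime: float, g: float, n: float) -> "OpticalProperties":
        """Construct from the reduced scattering coefficient via the
        similarity relation mus = mus' / (1 - g)."""
        return cls(mua=mua, mus=mus_prime / (1.0 - g), g=g, n=n)


#: Phantom characterization at 532 nm used throughout the package defaults.
PHANTOM_PROPERTIES = OpticalProperties.from_reduced(mua=0.348, mus_prime=2.81, g=0.86, n=1.4)


@dataclass(frozen=True)
class BeamSpec:
    """Circular top-hat beam at normal incidence.

    spot_diameter in mm; irradiation_fluence is the incident surface
    fluence F0 in J/cm^2.
    """

    spot_diameter: float
    irradiation_fluence: float
    profile: str = "circular_top_hat"

    def __post_init__(self):
        if self.spot_diameter <= 0:
            raise ValueError("spot_diameter must be positive")
        if self.irradiation_fluence <= 0:
            raise ValueError("irradiation_fluence must be positive")
        if self.profile != "circular_top_hat":
            raise ValueError("only the circular_top_hat profile is supported")


@dataclass(frozen=True)
class GridSpec:
    """Isotropic voxel grid: ``nx, ny`` lateral counts, ``nz`` depth count.

    Lateral coordinates are centered on the beam axis; depth spans
    [0, nz * voxel_size]. Odd lateral counts put a voxel column exactly on
    the axis (the convention used by :func:`extract_axial_slice`).
    """

    nx: int
    ny: int
    nz: int
    voxel_size: float

    def __post_init__(self):
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("voxel counts must be >= 1")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def lateral_extent(self) -> float:
        return min(self.nx, self.ny) * self.voxel_size

    @property
    def depth_extent(self) -> float:
        return self.nz * self.voxel_size

    @property
    def depths(self) -> np.ndarray:
        """Depth of each voxel center, mm."""
        return (np.arange(self.nz) + 0.5) * self.voxel_size

    @classmethod
    def for_beam(cls, spot_diameter: float, voxel_size: float = 0.05,
                 depth: float = 5.5, width: float | None = None) -> "GridSpec":
        """Default desk-scale grid: lateral width max(3 x spot, 6 mm),
        5.5 mm deep, forced-odd lateral counts."""
        if width is None:
            width = max(3.0 * spot_diameter, 6.0)
        n_lat = int(round(width / voxel_size))
        if n_lat % 2 == 0:
            n_lat += 1
        nz = int(round(depth / voxel_size))
        return cls(nx=n_lat, ny=n_lat, nz=nz, voxel_size=voxel_size)


@dataclass
class FluenceMap:
    """3-D fluence tally with geometry metadata.

    ``values`` has shape (nx, ny, nz); units are either "relative"
    (dimensionless, local fluence / incident fluence) or "J/cm^2".
    """

    values: np.ndarray
    grid: GridSpec
    photons_launched: int
    seed: int
    units: str = "relative"
    beam: BeamSpec | None = None
    audit: dict = field(default_factory=dict)

    @property
    def is_relative(self) -> bool:
        return self.units == "relative"


@dataclass(frozen=True)
class SlabMeasurement:
    """Total reflectance / transmittance of a laterally unbounded slab."""

    R_total: float
    T_total: float
    thickness: float

    def __post_init__(self):
        if not (0 <= self.R_total <= 1 and 0 <= self.T_total <= 1):
            raise ValueError("R_total and T_total must lie in [0, 1]")
        if self.R_total + self.T_total > 1 + 1e-9:
            raise ValueError("R_total + T_total must not exceed 1")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")


def simulate_fluence(props: OpticalProperties, beam: BeamSpec, grid: GridSpec,
                     n_photons: int, seed: int) -> FluenceMap:
    """Run the voxel Monte Carlo and return the relative fluence map.

    The tally is the track-length estimator (sum of weighted pathlengths per
    voxel / voxel volume), normalized by the incident photon fluence
    n_photons / beam area, so a non-scattering matched-index medium gives
    exp(-mua * z) on axis. Deterministic for a fixed (config, seed).
    """
    radius = beam.spot_diameter / 2.0
    half_x = grid.nx * grid.voxel_size / 2.0
    half_y = grid.ny * grid.voxel_size / 2.0
    if radius > min(half_x, half_y):
        raise ValueError("beam does not fit inside the lateral grid extent")
    if radius >= min(half_x, half_y) - grid.voxel_size:
        warnings.warn("beam touches the lateral grid edge; fluence near the "
                      "edge will be truncated", stacklevel=2)
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")

    tally = np.zeros((grid.nx, grid.ny, grid.nz), dtype=np.float64)
    audit = np.zeros(7, dtype=np.float64)
    _kernels.run_fluence(n_photons, seed, props.mua, props.mus, props.g,
                         props.n, radius, grid.nx, grid.ny, grid.nz,
                         grid.voxel_size, tally, audit)
    beam_area = np.pi * radius ** 2
    voxel_volume = grid.voxel_size ** 3
    values = tally * (beam_area / (n_photons * voxel_volume))
    audit_d = {
        "specular": audit[0] / n_photons,
        "absorbed": audit[1] / n_photons,
        "escaped_top": audit[2] / n_photons,
        "escaped_bottom": audit[3] / n_photons,
        "escaped_lateral": audit[4] / n_photons,
        "roulette_killed": audit[5] / n_photons,
        "roulette_created": audit[6] / n_photons,
    }
    return FluenceMap(values=values, grid=grid, photons_launched=n_photons,
                      seed=seed, units="relative", beam=beam, audit=audit_d)


def simulate_slab_RT(props: OpticalProperties, thickness: float,
                     n_photons: int, seed: int) -> SlabMeasurement:
    """Forward model of a double-integrating-sphere measurement on a bare
    slab: total reflected fraction (specular included) and total
    transmitted fraction for a laterally unbounded slab in air."""
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    R, T, _ = _kernels.run_slab(n_photons, seed, props.mua, props.mus,
                                props.g, props.n, thickness)
    return SlabMeasurement(R_total=min(R, 1.0), T_total=min(T, 1.0),
                           thickness=thickness)


def scale_to_absolute(fmap: FluenceMap, beam: BeamSpec) -> FluenceMap:
    """Multiply a relative map by the irradiation fluence -> J/cm^2."""
    if not fmap.is_relative:
        raise ValueError("map is already in absolute units; refusing to "
                         "scale twice")
    return replace(fmap, values=fmap.values * beam.irradiation_fluence,
                   units="J/cm^2", beam=beam)


def extract_axial_slice(fmap: FluenceMap) -> np.ndarray:
    """Lateral-by-depth fluence plane through the beam axis.

    Returns an array of shape (nx, nz) taken at the central y voxel column
    (ny is odd by the :meth:`GridSpec.for_beam` construction; for even ny
    the column just below the axis is used)."""
    return fmap.values[:, fmap.grid.ny // 2, :].copy()
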