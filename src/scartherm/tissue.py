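"""Tissue geometry, material parameters, and the axisymmetric material grid.

The simulated specimen is a skin cylinder (20 mm diameter, 4 mm thick)
irradiated from above on its axis.  A single enlarged blood vessel is
modelled as a coaxial cylinder starting at the irradiated surface
(diameter 1.0 mm for hypertrophic scar, 0.6 mm for normal skin, 2.0 mm
deep).  Everything is rotationally symmetric about the beam axis, so the
model is solved on a 2-D cell-centered (r, z) grid with z = 0 at the
irradiated surface, increasing downward.

Optical parameters (absorption/scattering coefficients and surface
reflectivity at the pulsed-dye-laser wavelength) differ between scar and
normal skin; thermophysical closure values (density, specific heat,
conductivity) are standard dermal literature values shared by both
presets and overridable through the config layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MaterialProperties",
    "TissueDomain",
    "GridSpec",
    "MaterialGrid",
    "ConfigurationError",
    "PRESETS",
    "TISSUE",
    "VESSEL",
    "build_domain",
    "material_for",
]

TISSUE = "tissue"
VESSEL = "vessel"


class ConfigurationError(ValueError):
    """Raised for unknown presets/labels or incomplete material closures."""


@dataclass(frozen=True)
class MaterialProperties:
    """Optical and thermophysical parameters of one material.

    Units follow the field's mixed conventions: optical coefficients in
    1/cm, thermophysical quantities in SI, temperatures in degrees C.

    Attributes
    ----------
    mu_a, mu_s : float
        Absorption and scattering coefficients (1/cm).
    R : float
        Diffuse surface reflectivity (dimensionless fraction).
    rho, c, k : float
        Density (kg/m^3), specific heat (J/(kg K)), thermal
        conductivity (W/(m K)).
    rho_b, c_b, w_b : float
        Blood density (kg/m^3), blood specific heat (J/(kg K)), blood
        perfusion rate (1/s) entering the Pennes sink term.
    T_art, T0, T1 : float
        Arterial, initial-tissue, and ambient temperatures (degC).
    """

    mu_a: float
    mu_s: float
    R: float
    rho: float
    c: float
    k: float
    rho_b: float = 1000.0
    c_b: float = 4180.0
    w_b: float = 6.4e-3
    T_art: float = 37.0
    T0: float = 37.0
    T1: float = 25.0

    def __post_init__(self) -> None:
        for name in ("mu_a", "mu_s", "rho", "c", "k", "rho_b", "c_b", "w_b"):
            v = getattr(self, name)
            if v is None:
                raise ConfigurationError(f"material closure parameter '{name}' is missing")
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"material parameter '{name}' must be >= 0, got {v!r}")
        if not 0.0 <= self.R < 1.0:
            raise ConfigurationError(f"reflectivity R must lie in [0, 1), got {self.R!r}")
        for name in ("T_art", "T0"):
            v = getattr(self, name)
            if not 30.0 <= v <= 45.0:
                raise ConfigurationError(f"{name}={v!r} degC is outside the physiologic range 30-45")

    @property
    def mu_t(self) -> float:
        """Total attenuation coefficient mu_a + mu_s (1/cm)."""
        return self.mu_a + self.mu_s

    @property
    def rho_c(self) -> float:
        """Volumetric heat capacity rho*c (J/(m^3 K))."""
        return self.rho * self.c

    @property
    def perfusion_coefficient(self) -> float:
        """rho_b * c_b * w_b (W/(m^3 K)), the Pennes sink coefficient."""
        return self.rho_b * self.c_b * self.w_b


# Dermal closure values shared by both presets (literature skin values;
# the optical table this model is built around does not fix them).
DEFAULT_CLOSURE = {"rho": 1200.0, "c": 3600.0, "k": 0.5}

# Digitized optical parameter sets for normal skin and hypertrophic scar
# at the pulsed-dye-laser wavelength, plus shared blood/ambient values.
PRESETS: dict[str, dict] = {
    "hps": {
        "optics": {"mu_a": 5.574, "mu_s": 118.37, "R": 0.2},
        "vessel_radius_mm": 0.5,
    },
    "normal_skin": {
        "optics": {"mu_a": 1.395, "mu_s": 183.92, "R": 0.58},
        "vessel_radius_mm": 0.3,
    },
}


def material_for(preset: str, label: str = TISSUE, closure: dict | None = None) -> MaterialProperties:
    """Material parameter set for ``label`` cells of a ``preset`` domain.

    Vessel cells take blood thermophysical values (rho_b, c_b) but share
    the enclosing tissue's optical properties and conductivity: the beam
    sees one optical medium, while the vessel lumen carries the heat
    capacity of blood.

    Parameters
    ----------
    preset : {"hps", "normal_skin"}
    label : {"tissue", "vessel"}
    closure : dict, optional
        Overrides for the thermophysical closure (rho, c, k).
    """
    if preset not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {preset!r}; expected one of {sorted(PRESETS)}"
        )
    if label not in (TISSUE, VESSEL):
        raise ConfigurationError(f"unknown material label {label!r}")
    cl = dict(DEFAULT_CLOSURE)
    if closure:
        cl.update(closure)
    missing = [k for k in ("rho", "c", "k") if cl.get(k) is None]
    if missing:
        raise ConfigurationError(f"missing closure parameter(s): {', '.join(missing)}")
    props = MaterialProperties(**PRESETS[preset]["optics"], rho=cl["rho"], c=cl["c"], k=cl["k"])
    if label == VESSEL:
        props = replace(props, rho=props.rho_b, c=props.c_b)
    return props


@dataclass(frozen=True)
class GridSpec:
    """Cell-centered grid resolution.

    Radial spacing is uniform (``dr_mm``).  The axial mesh is either
    uniform (give ``dz_mm``) or geometrically graded from the irradiated
    surface (give ``nz`` and ``dz0_mm``): the optical penetration depth
    1/mu_t is tens of micrometres, far below a practical uniform
    spacing, so the default preset grids grade the mesh to resolve the
    absorption layer while keeping the cell count modest.
    """

    dr_mm: float = 0.1
    dz_mm: float | None = None
    nz: int | None = None
    dz0_mm: float | None = None

    def __post_init__(self) -> None:
        if self.dr_mm <= 0:
            raise ConfigurationError("dr_mm must be positive")
        if self.dz_mm is not None:
            if self.dz_mm <= 0:
                raise ConfigurationError("dz_mm must be positive")
        elif self.nz is None or self.dz0_mm is None:
            raise ConfigurationError("give either dz_mm (uniform) or nz + dz0_mm (graded)")
        elif self.nz < 3 or self.dz0_mm <= 0:
            raise ConfigurationError("graded grid needs nz >= 3 and dz0_mm > 0")

    def axial_spacings(self, depth_mm: float) -> np.ndarray:
        """Per-cell axial thicknesses (mm), top (z=0) first."""
        if self.dz_mm is not None:
            nz = int(round(depth_mm / self.dz_mm))
            if nz < 3:
                raise ConfigurationError("fewer than 3 axial cells; refine dz_mm")
            return np.full(nz, depth_mm / nz)
        nz, dz0 = self.nz, self.dz0_mm
        if nz * dz0 >= depth_mm:
            return np.full(nz, depth_mm / nz)  # uniform already finer than requested
        # solve dz0 * (g^nz - 1)/(g - 1) = depth for the growth factor g
        from scipy.optimize import brentq

        g = brentq(lambda g: dz0 * (g**nz - 1.0) / (g - 1.0) - depth_mm, 1.0 + 1e-9, 2.0)
        dz = dz0 * g ** np.arange(nz)
        return dz * (depth_mm / dz.sum())  # absorb the residual rounding


@dataclass(frozen=True)
class TissueDomain:
    """Axisymmetric cylindrical simulation domain (lengths in mm)."""

    radius: float = 10.0
    depth: float = 4.0
    vessel_radius: float = 0.5
    vessel_depth: float = 2.0
    vessel_top_offset: float = 0.0
    preset: str = "hps"

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.depth <= 0:
            raise ConfigurationError("domain radius and depth must be positive")
        if not 0 <= self.vessel_radius < self.radius:
            raise ConfigurationError("vessel radius must satisfy 0 <= r_v < domain radius")
        if self.vessel_top_offset + self.vessel_depth > self.depth:
            raise ConfigurationError("vessel must fit within the domain depth")


class MaterialGrid:
    """Material labels, properties, and cell volumes on the (r, z) grid.

    Arrays are indexed ``[j, i]`` with j the axial (depth) index and i
    the radial index.  Cell volumes are annular: V = 2*pi*r_i*dr*dz_j.
    Geometry arrays are exposed in metres for the solver; the domain
    object keeps millimetres for human-facing I/O.
    """

    def __init__(self, domain: TissueDomain, spec: GridSpec, closure: dict | None = None):
        self.domain = domain
        self.spec = spec
        dz_mm = spec.axial_spacings(domain.depth)
        nr = int(round(domain.radius / spec.dr_mm))
        if nr < 3:
            raise ConfigurationError("fewer than 3 radial cells; refine dr_mm")
        self.nr = nr
        self.nz = len(dz_mm)
        self.dr_m = domain.radius / nr * 1e-3
        self.dz_m = dz_mm * 1e-3
        self.r_m = (np.arange(nr) + 0.5) * self.dr_m
        self.z_m = (np.cumsum(self.dz_m) - self.dz_m / 2.0)
        self.z_edges_m = np.concatenate([[0.0], np.cumsum(self.dz_m)])
        if spec.dr_mm > domain.vessel_radius > 0:
            warnings.warn(
                f"radial spacing {spec.dr_mm} mm is coarser than the vessel radius "
                f"{domain.vessel_radius} mm; the vessel is unresolved",
                stacklevel=2,
            )
        in_r = self.r_m <= domain.vessel_radius * 1e-3
        top = domain.vessel_top_offset * 1e-3
        in_z = (self.z_m >= top) & (self.z_m <= top + domain.vessel_depth * 1e-3)
        self.labels = np.where(in_z[:, None] & in_r[None, :], VESSEL, TISSUE)
        self.volumes = 2.0 * np.pi * self.r_m[None, :] * self.dr_m * self.dz_m[:, None]

        self.materials = {
            TISSUE: material_for(domain.preset, TISSUE, closure),
            VESSEL: material_for(domain.preset, VESSEL, closure),
        }
        self.rho_c = np.where(self.labels == VESSEL,
                              self.materials[VESSEL].rho_c,
                              self.materials[TISSUE].rho_c)
        self.k = np.where(self.labels == VESSEL,
                          self.materials[VESSEL].k,
                          self.materials[TISSUE].k)
        # the perfusion sink applies everywhere, vessel included
        self.perfusion = np.full((self.nz, nr), self.materials[TISSUE].perfusion_coefficient)

    @property
    def tissue(self) -> MaterialProperties:
        return self.materials[TISSUE]

    def region_mask(self, region: str) -> np.ndarray:
        """Boolean cell mask for ``region``.

        ``scar_subvolume`` is the lesion a clinician targets: every
        tissue-labelled cell (the vessel lumen excluded);
        ``whole_domain`` is everything.
        """
        if region == "whole_domain":
            return np.ones_like(self.volumes, dtype=bool)
        if region == "scar_subvolume":
            return self.labels == TISSUE
        raise ConfigurationError(f"unknown region {region!r}")

    def total_volume(self) -> float:
        """Sum of cell volumes (m^3); equals the analytic cylinder volume."""
        return float(self.volumes.sum())


def build_domain(
    preset: str,
    resolution: GridSpec | None = None,
    closure: dict | None = None,
    **domain_overrides,
) -> tuple[TissueDomain, MaterialGrid]:
    """Construct the preset cylinder domain and its material grid.

    Parameters
    ----------
    preset : {"hps", "normal_skin"}
        Chooses optics and vessel diameter (1.0 mm scar, 0.6 mm normal).
    resolution : GridSpec, optional
        Defaults to dr = 0.1 mm with a graded axial mesh (120 cells,
        5 um at the surface) resolving the optical absorption layer.
    closure : dict, optional
        Thermophysical closure overrides (rho, c, k).
    """
    if preset not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {preset!r}; expected one of {sorted(PRESETS)}"
        )
    if resolution is None:
        resolution = GridSpec(dr_mm=0.1, nz=120, dz0_mm=5e-3)
    kwargs = {"vessel_radius": PRESETS[preset]["vessel_radius_mm"], **domain_overrides}
    domain = TissueDomain(preset=preset, **kwargs)
    return domain, MaterialGrid(domain, resolution, closure)
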