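"""X-ray physics for the virtual CT scanner.

Materials are elemental mixtures with a mass density; their relative
electron density (RED) is the electron density per unit volume relative
to liquid water at 1.0 g/cm3, the quantity a radiotherapy dose engine
needs per voxel.

Photon attenuation in the diagnostic range (10-150 keV) is modelled as
the sum of Klein-Nishina incoherent scattering off Z free electrons per
atom and power-law photoelectric and coherent terms whose constants were
fitted to standard water and aluminium mass-attenuation values (the fit
reproduces the embedded water anchors to better than 1%).  Per-element
tables are evaluated on a 1 keV grid and interpolated log-log.

Tube spectra follow a Kramers bremsstrahlung shape with configurable
aluminium filtration, optional tungsten characteristic lines, and
energy-integrating detector weighting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfigurationError",
    "Material",
    "Spectrum",
    "AttenuationTable",
    "ATTENUATION",
    "compute_red",
    "mass_attenuation",
    "linear_attenuation",
    "make_spectrum",
    "material_from_red",
    "material_library",
    "WATER",
    "WATER_REFERENCE_MU_RHO",
]


class ConfigurationError(ValueError):
    """Invalid material, spectrum or scan configuration."""


# (atomic number Z, standard atomic weight A) per element symbol.
ELEMENTS: dict[str, tuple[int, float]] = {
    "H": (1, 1.008), "C": (6, 12.011), "N": (7, 14.007), "O": (8, 15.999),
    "Na": (11, 22.990), "Mg": (12, 24.305), "Al": (13, 26.982),
    "P": (15, 30.974), "S": (16, 32.06), "Cl": (17, 35.45),
    "K": (19, 39.098), "Ca": (20, 40.078), "Ti": (22, 47.867),
    "Cr": (24, 51.996), "Fe": (26, 55.845), "Ni": (28, 58.693),
    "Cu": (29, 63.546), "Zn": (30, 65.38),
}

AVOGADRO = 6.02214076e23  # 1/mol

# Cross-section model constants (cm^2/atom with E in keV), least-squares
# fitted to NIST water and aluminium mass-attenuation anchors.
_PE_COEFF = 10.0 ** -21.54582984
_PE_Z_EXP = 3.21334865
_PE_E_EXP = 3.93441075
_COH_COEFF = 10.0 ** -22.87421267
_COH_Z_EXP = 4.34627072
_COH_E_EXP = 2.94884239

ENERGY_MIN_KEV = 10.0
ENERGY_MAX_KEV = 150.0

# NIST water mass attenuation (cm^2/g), kept as frozen reference anchors.
WATER_REFERENCE_MU_RHO = {40.0: 0.2683, 60.0: 0.2059, 80.0: 0.1837, 100.0: 0.1707}


def klein_nishina_cross_section(energy_kev):
    """Total Klein-Nishina cross section per electron (cm^2)."""
    k = np.asarray(energy_kev, dtype=float) / 511.0
    r_e2 = 7.94079e-26  # classical electron radius squared, cm^2
    t1 = (1 + k) / k**2 * (2 * (1 + k) / (1 + 2 * k) - np.log1p(2 * k) / k)
    t2 = np.log1p(2 * k) / (2 * k)
    t3 = -(1 + 3 * k) / (1 + 2 * k) ** 2
    return 2 * np.pi * r_e2 * (t1 + t2 + t3)


def _element_mu_rho(symbol: str, energy_kev) -> np.ndarray:
    """Model mass attenuation coefficient of one element, cm^2/g."""
    if symbol not in ELEMENTS:
        raise ConfigurationError(f"unknown element symbol {symbol!r}")
    z, a = ELEMENTS[symbol]
    e = np.asarray(energy_kev, dtype=float)
    sigma = (
        z * klein_nishina_cross_section(e)
        + _PE_COEFF * z**_PE_Z_EXP / e**_PE_E_EXP
        + _COH_COEFF * z**_COH_Z_EXP / e**_COH_E_EXP
    )
    return AVOGADRO / a * sigma


class AttenuationTable:
    """Per-element (energy, mass attenuation) tables with log-log interpolation.

    Tables span 10-150 keV on a 1 keV grid; lookups outside that range
    raise, matching the validity range of the fitted cross-section model.
    """

    def __init__(self, symbols=tuple(ELEMENTS)):
        self.energies = np.arange(ENERGY_MIN_KEV, ENERGY_MAX_KEV + 0.5, 1.0)
        self._log_e = np.log(self.energies)
        self.tables = {s: _element_mu_rho(s, self.energies) for s in symbols}
        if any((t <= 0).any() for t in self.tables.values()):
            raise ConfigurationError("attenuation table has non-positive entries")

    def mu_rho(self, symbol: str, energy_kev) -> np.ndarray:
        e = np.asarray(energy_kev, dtype=float)
        if np.any(e < ENERGY_MIN_KEV) or np.any(e > ENERGY_MAX_KEV):
            raise ValueError(
                f"energy outside tabulated range "
                f"[{ENERGY_MIN_KEV}, {ENERGY_MAX_KEV}] keV"
            )
        if symbol not in self.tables:
            raise ConfigurationError(f"unknown element symbol {symbol!r}")
        logm = np.interp(np.log(e), self._log_e, np.log(self.tables[symbol]))
        return np.exp(logm)


#: Shared table instance used throughout the package.
ATTENUATION = AttenuationTable()


@dataclass(frozen=True)
class Material:
    """Elemental mixture with a mass density in g/cm3."""

    name: str
    composition: dict[str, float]
    mass_density: float

    def __post_init__(self):
        if self.mass_density <= 0:
            raise ConfigurationError(f"{self.name}: mass density must be positive")
        total = 0.0
        for sym, w in self.composition.items():
            if sym not in ELEMENTS:
                raise ConfigurationError(f"{self.name}: unknown element {sym!r}")
            if w < 0:
                raise ConfigurationError(f"{self.name}: negative mass fraction {sym}")
            total += w
        if abs(total - 1.0) > 1e-6:
            raise ConfigurationError(
                f"{self.name}: mass fractions sum to {total}, expected 1"
            )

    @property
    def electrons_per_gram(self) -> float:
        return AVOGADRO * sum(
            w * ELEMENTS[s][0] / ELEMENTS[s][1] for s, w in self.composition.items()
        )

    @property
    def red(self) -> float:
        return compute_red(self)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "composition": dict(self.composition),
            "mass_density": self.mass_density,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Material":
        return cls(d["name"], dict(d["composition"]), float(d["mass_density"]))


WATER = Material("water", {"H": 2 * 1.008 / 18.015, "O": 15.999 / 18.015}, 1.0)
_WATER_ELECTRON_DENSITY = WATER.mass_density * WATER.electrons_per_gram  # e/cm3


def compute_red(material: Material) -> float:
    """Relative electron density: electrons/cm3 relative to water at 1 g/cm3."""
    return material.mass_density * material.electrons_per_gram / _WATER_ELECTRON_DENSITY


def mass_attenuation(material: Material, energy_kev) -> np.ndarray:
    """Mixture-rule mass attenuation coefficient, cm^2/g."""
    return sum(
        w * ATTENUATION.mu_rho(sym, energy_kev)
        for sym, w in material.composition.items()
    )


def linear_attenuation(material: Material, energy_kev) -> np.ndarray:
    """Linear attenuation coefficient mu = (mu/rho) * rho, 1/cm."""
    return mass_attenuation(material, energy_kev) * material.mass_density


def material_from_red(name: str, composition: dict[str, float], red: float) -> Material:
    """Build a material with the density that yields the requested RED.

    The composition is fixed and the mass density adjusted, mirroring how
    tissue-substitute phantom inserts are manufactured to a nominal RED.
    """
    probe = Material(name, composition, 1.0)
    density = red * _WATER_ELECTRON_DENSITY / probe.electrons_per_gram
    return Material(name, composition, density)


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

_AL_DENSITY = 2.699  # g/cm3

# Tungsten anode K-shell lines (keV, relative strength); only emitted when
# the tube voltage exceeds the K edge at 69.5 keV.
_W_LINES = ((59.3, 1.0), (67.2, 0.35), (69.1, 0.25))
_W_K_EDGE = 69.5


@dataclass(frozen=True)
class Spectrum:
    """Detector-weighted relative photon fluence on a keV grid."""

    kvp: float
    energies: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if e.size < 10:
            raise ConfigurationError("spectrum needs at least 10 energy bins")
        if e.max() > self.kvp + 1e-9:
            raise ConfigurationError("spectrum energies exceed the tube voltage")
        if (w < 0).any():
            raise ConfigurationError("negative spectrum weights")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError("spectrum weights must sum to 1")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w)

    @property
    def mean_energy(self) -> float:
        return float(np.sum(self.energies * self.weights))

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.energies, self.weights]),
            delimiter=",",
            header="energy_keV,weight",
            comments="",
        )

    @classmethod
    def from_csv(cls, path, kvp=None) -> "Spectrum":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        e, w = data[:, 0], data[:, 1]
        return cls(kvp=float(kvp if kvp is not None else e.max()), energies=e, weights=w / w.sum())


STANDARD_KVPS = (80, 100, 120, 140)


def make_spectrum(kvp: float, filtration_mm_al: float = 10.0,
                  characteristic_lines: bool = False) -> Spectrum:
    """Filtered Kramers bremsstrahlung spectrum with detector weighting.

    Photon fluence ~ (kvp/E - 1), attenuated by the stated aluminium
    filtration, then weighted by E for an energy-integrating detector and
    normalized.  1 keV bins from 10 keV to the tube voltage.  The default
    filtration is the aluminium-equivalent of a CT scanner's total
    central-ray filtration (inherent plus bow-tie center), which is far
    heavier than a radiographic tube port.
    """
    if filtration_mm_al < 0:
        raise ConfigurationError("filtration must be non-negative")
    if kvp not in STANDARD_KVPS:
        warnings.warn(f"non-standard tube voltage {kvp} kVp", stacklevel=2)
    energies = np.arange(ENERGY_MIN_KEV, float(kvp) + 0.5, 1.0)
    fluence = np.maximum(kvp / energies - 1.0, 0.0)
    mu_al = ATTENUATION.mu_rho("Al", energies) * _AL_DENSITY
    fluence = fluence * np.exp(-mu_al * filtration_mm_al / 10.0)
    if characteristic_lines and kvp > _W_K_EDGE:
        brems_peak = fluence.max()
        for line_e, strength in _W_LINES:
            idx = int(round(line_e - ENERGY_MIN_KEV))
            fluence[idx] += strength * brems_peak
    weighted = fluence * energies  # energy-integrating detector
    return Spectrum(kvp=float(kvp), energies=energies, weights=weighted / weighted.sum())


# ---------------------------------------------------------------------------
# Material library
# ---------------------------------------------------------------------------

# Tissue-substitute compositions (ICRU-style mass fractions).  Densities of
# the phantom inserts are derived from their nominal REDs, the way tissue
# substitutes are specified by manufacturers.
_SOFT_TISSUE = {"H": 0.102, "C": 0.143, "N": 0.034, "O": 0.708,
                "Na": 0.001, "P": 0.002, "S": 0.003, "Cl": 0.002, "K": 0.005}
_ADIPOSE = {"H": 0.114, "C": 0.598, "N": 0.007, "O": 0.278,
            "Na": 0.001, "S": 0.001, "Cl": 0.001}
_BREAST = {"H": 0.106, "C": 0.332, "N": 0.030, "O": 0.527,
           "Na": 0.001, "P": 0.001, "S": 0.002, "Cl": 0.001}
_LIVER = {"H": 0.102, "C": 0.139, "N": 0.030, "O": 0.718,
          "Na": 0.002, "P": 0.003, "S": 0.003, "Cl": 0.002, "K": 0.001}
_CORTICAL_BONE = {"H": 0.034, "C": 0.155, "N": 0.042, "O": 0.435,
                  "Na": 0.001, "Mg": 0.002, "P": 0.103, "S": 0.003, "Ca": 0.225}
_EPOXY_WATER_SUB = {"H": 0.0809, "C": 0.6722, "N": 0.0240, "O": 0.1984,
                    "Cl": 0.0013, "Ca": 0.0232}
# Gypsum CaSO4.2H2O mass fractions from the formula (M = 172.164 g/mol).
_GYPSUM = {"Ca": 40.078 / 172.164, "S": 32.06 / 172.164,
           "O": 6 * 15.999 / 172.164, "H": 4 * 1.008 / 172.164}
_CELLULOSE = {"H": 0.0622, "C": 0.4445, "O": 0.4933}
_AIR = {"N": 0.765, "O": 0.235}
_STEEL = {"Fe": 0.71, "Cr": 0.17, "Ni": 0.12}
_BRASS = {"Cu": 0.63, "Zn": 0.37}


def _graded_bone(name: str, target_red: float) -> Material:
    """Volumetric water/cortical-bone mixture hitting the target RED.

    Electron-density phantom bone inserts are engineered to mimic the
    attenuation-vs-RED relation of real skeletal tissue, i.e. to lie on
    the water/bone two-material manifold; a volume mixture of water and
    the RED-1.7 cortical reference bone reproduces that by construction.
    """
    cortical = material_from_red("cortical_bone", dict(_CORTICAL_BONE), 1.70)
    v = (target_red - 1.0) / (cortical.red - 1.0)
    if not 0.0 <= v <= 1.0:
        raise ConfigurationError(f"{name}: RED {target_red} outside [1, 1.7]")
    m_water = (1 - v) * WATER.mass_density
    m_bone = v * cortical.mass_density
    total = m_water + m_bone
    comp: dict[str, float] = {}
    for mat, m in ((WATER, m_water), (cortical, m_bone)):
        for sym, w in mat.composition.items():
            comp[sym] = comp.get(sym, 0.0) + w * m / total
    return Material(name, comp, total)


def material_library() -> dict[str, Material]:
    """Default materials: phantom body, tissue inserts and metals.

    Insert REDs follow the manufacturer reference values of the emulated
    electron-density phantoms (e.g. titanium 3.74, stainless steel 6.92).
    """
    lib = {
        "water": WATER,
        "air": Material("air", _AIR, 1.2e-3),
        "solid_water": material_from_red("solid_water", _EPOXY_WATER_SUB, 1.00),
        "lung_inhale": material_from_red("lung_inhale", _SOFT_TISSUE, 0.20),
        "lung_exhale": material_from_red("lung_exhale", _SOFT_TISSUE, 0.50),
        "adipose": material_from_red("adipose", _ADIPOSE, 0.95),
        "breast": material_from_red("breast", _BREAST, 0.98),
        "muscle": material_from_red("muscle", _SOFT_TISSUE, 1.04),
        "liver": material_from_red("liver", _LIVER, 1.05),
        "bone_200": _graded_bone("bone_200", 1.12),
        "bone_800": _graded_bone("bone_800", 1.46),
        "bone_1250": _graded_bone("bone_1250", 1.70),
        "cortical_bone": material_from_red("cortical_bone", dict(_CORTICAL_BONE), 1.70),
        "titanium": material_from_red("titanium", {"Ti": 1.0}, 3.74),
        "steel": material_from_red("steel", _STEEL, 6.92),
        "brass": material_from_red("brass", _BRASS, 7.00),
        # Cast plaster and cork densities hand-set to the REDs the slab
        # phantom inserts exhibit (1.37 and 0.26).
        "plaster": Material("plaster", _GYPSUM, 1.4884),
        "cork": Material("cork", _CELLULOSE, 0.2720),
    }
    return lib


def materials_to_json(path, materials: dict[str, Material]) -> None:
    with open(path, "w") as fh:
        json.dump({k: m.to_dict() for k, m in materials.items()}, fh, indent=1)


def materials_from_json(path) -> dict[str, Material]:
    with open(path) as fh:
        raw = json.load(fh)
    return {k: Material.from_dict(d) for k, d in raw.items()}
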