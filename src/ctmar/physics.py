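"""Energy-dependent attenuation model and polychromatic tube spectra.

The attenuation of every material is described by a two-basis model

    mu(E) = a_pe * (E / E0)**-3 + a_c * f_KN(E) / f_KN(E0)

where the first term is the photoelectric contribution (the steep ~E^-3
component responsible for beam hardening) and the second follows the total
Klein-Nishina cross-section shape of Compton scattering.  Both basis
functions are normalized to 1 at the reference energy ``E0 = 70 keV``, so a
material's ``(a_pe, a_c)`` pair is its photoelectric/Compton split of
mu(70 keV) in cm^-1.  The water coefficients are anchored so that
mu_water(70 keV) = 0.1928 cm^-1, the fixed point of the Hounsfield
calibration used throughout the package.

Tube spectra are analytic: a Kramers bremsstrahlung shape on [20, kVp] keV,
attenuated by an aluminium-equivalent inherent filtration and, for the
tin-filtered 140 kV setting, an additional 0.4 mm Sn term.  Only the
*relative* hardening between the 100 kV and Sn140 kV beams matters to the
artefact mechanisms studied here, so no attempt is made to match a
manufacturer spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "Material",
    "Spectrum",
    "REFERENCE_KEV",
    "WATER_MU_70KEV",
    "MATERIALS",
    "METAL_NAMES",
    "attenuation",
    "mu_water",
    "make_spectrum",
    "klein_nishina_ratio",
    "basis_functions",
    "load_material_table",
    "dump_material_table",
]

#: Reference energy of the two-basis model (keV).
REFERENCE_KEV = 70.0

#: Linear attenuation of water at the reference energy (cm^-1); the HU anchor.
WATER_MU_70KEV = 0.1928

_ELECTRON_REST_KEV = 510.998950


@dataclass(frozen=True)
class Material:
    """A material of the digital phantoms.

    Parameters
    ----------
    name:
        Label used in phantom grids and config files.
    density:
        Mass density in g/cm^3 (metadata; attenuation is carried by the
        basis coefficients directly).
    a_pe:
        Photoelectric basis coefficient, cm^-1 at 70 keV.
    a_c:
        Compton (Klein-Nishina) basis coefficient, cm^-1 at 70 keV.
    """

    name: str
    density: float
    a_pe: float
    a_c: float

    def __post_init__(self) -> None:
        if self.a_pe < 0 or self.a_c < 0:
            raise ValueError(f"{self.name}: basis coefficients must be >= 0")
        if self.name != "air" and self.density <= 0:
            raise ValueError(f"{self.name}: density must be > 0")

    @property
    def mu_reference(self) -> float:
        """mu at the reference energy (= a_pe + a_c by construction)."""
        return self.a_pe + self.a_c


def klein_nishina_total(energy_kev):
    """Total Klein-Nishina cross-section (arbitrary units) at ``energy_kev``."""
    eps = np.asarray(energy_kev, dtype=float) / _ELECTRON_REST_KEV
    t1 = (1.0 + eps) / eps**2 * (2.0 * (1.0 + eps) / (1.0 + 2.0 * eps)
                                 - np.log1p(2.0 * eps) / eps)
    t2 = np.log1p(2.0 * eps) / (2.0 * eps)
    t3 = -(1.0 + 3.0 * eps) / (1.0 + 2.0 * eps) ** 2
    return t1 + t2 + t3


def klein_nishina_ratio(energy_kev):
    """Klein-Nishina shape normalized to 1 at the reference energy."""
    return klein_nishina_total(energy_kev) / klein_nishina_total(REFERENCE_KEV)


def basis_functions(energy_kev):
    """Return ``(b_pe, b_c)`` basis values at ``energy_kev``.

    ``b_pe(E) = (E/E0)^-3`` and ``b_c(E)`` is the normalized Klein-Nishina
    shape; both equal 1 at E0 = 70 keV.  Shared by the simulator and the
    dual-energy decomposition so that noiseless decomposition is exact.
    """
    e = np.asarray(energy_kev, dtype=float)
    return (e / REFERENCE_KEV) ** -3, klein_nishina_ratio(e)


# Editable material table.  Coefficients are stylized, not tabulated NIST
# data: water is pinned to the HU anchor, tissues sit at plausible HU, and
# the three metals are tiered (titanium < steel < amalgam) so that implant
# density can drive the iterative-MAR cycle count.
MATERIALS: dict[str, Material] = {
    "air":          Material("air",          0.0012, 2.0e-5, 6.0e-5),
    "water":        Material("water",        1.00,   0.0078, 0.1850),
    "soft_tissue":  Material("soft_tissue",  1.04,   0.0090, 0.1890),
    "bone":         Material("bone",         1.85,   0.0600, 0.3000),
    "iodine_blood": Material("iodine_blood", 1.05,   0.0500, 0.1900),
    "titanium":     Material("titanium",     4.50,   2.3000, 1.5500),
    "steel":        Material("steel",        7.90,   4.8000, 2.4000),
    "amalgam":      Material("amalgam",      10.0,   9.5000, 3.2000),
    # filtration-only materials (never placed in phantoms)
    "aluminium":    Material("aluminium",    2.70,   0.0500, 0.1550),
    "tin":          Material("tin",          7.31,   6.5000, 2.3000),
}

#: Materials counted as implant metal by phantoms and the MAR chain.
METAL_NAMES = frozenset({"titanium", "steel", "amalgam"})


def attenuation(material: Material | str, energy_kev: float):
    """Linear attenuation coefficient mu(E) in cm^-1.

    Raises
    ------
    ValueError
        If any energy lies outside (10, 150] keV.
    """
    if isinstance(material, str):
        material = MATERIALS[material]
    e = np.asarray(energy_kev, dtype=float)
    if np.any(e <= 10.0) or np.any(e > 150.0):
        raise ValueError(f"energy must lie in (10, 150] keV, got {energy_kev}")
    b_pe, b_c = basis_functions(e)
    out = material.a_pe * b_pe + material.a_c * b_c
    return float(out) if np.isscalar(energy_kev) else out


def mu_water(energy_kev: float):
    """Water attenuation at ``energy_kev`` (cm^-1); the HU calibration anchor."""
    return attenuation(MATERIALS["water"], energy_kev)


@dataclass(frozen=True)
class Spectrum:
    """Discrete polychromatic tube spectrum.

    ``energies`` are keV bin centers (ascending), ``weights`` the relative
    fluence per bin normalized to sum 1.
    """

    energies: np.ndarray
    weights: np.ndarray
    kvp_label: str

    def __post_init__(self) -> None:
        if abs(float(self.weights.sum()) - 1.0) > 1e-12:
            raise ValueError("spectrum weights must sum to 1")
        if np.any(self.weights < 0):
            raise ValueError("spectrum weights must be non-negative")

    @property
    def mean_energy(self) -> float:
        """Fluence-weighted mean energy (keV); the effective energy used
        for HU calibration of polyenergetic reconstructions."""
        return float(np.sum(self.energies * self.weights))


_KVP = {"kv100": 100.0, "kv140Sn": 140.0}

#: Aluminium-equivalent inherent filtration of the tube (cm).
INHERENT_FILTRATION_CM = 0.5
#: Added tin filter thickness for the Sn140 setting (cm) — 0.4 mm Sn.
TIN_FILTER_CM = 0.04


def make_spectrum(kvp_label: str, n_bins: int = 50) -> Spectrum:
    """Build the polychromatic spectrum for one tube setting.

    Kramers bremsstrahlung fluence ``(E_max - E)/E`` on [20, kVp] keV,
    multiplied by aluminium inherent filtration and — for ``kv140Sn`` — the
    0.4 mm tin filter that hardens the high-kV beam.

    Raises
    ------
    KeyError
        For an unknown ``kvp_label``.
    ValueError
        If ``n_bins`` < 5.
    """
    if kvp_label not in _KVP:
        raise KeyError(f"unknown kvp_label {kvp_label!r}; expected one of {sorted(_KVP)}")
    if n_bins < 5:
        raise ValueError("n_bins must be >= 5")
    e_max = _KVP[kvp_label]
    edges = np.linspace(20.0, e_max, n_bins + 1)
    energies = 0.5 * (edges[:-1] + edges[1:])
    w = (e_max - energies) / energies  # Kramers fluence shape
    w = w * np.exp(-attenuation("aluminium", energies) * INHERENT_FILTRATION_CM)
    if kvp_label == "kv140Sn":
        w = w * np.exp(-attenuation("tin", energies) * TIN_FILTER_CM)
    w = w / w.sum()
    return Spectrum(energies=energies, weights=w, kvp_label=kvp_label)


def dump_material_table(path: str | Path, table: Mapping[str, Material] | None = None) -> None:
    """Write the material table as editable YAML."""
    table = MATERIALS if table is None else table
    payload = {
        name: {"density": m.density, "a_pe": m.a_pe, "a_c": m.a_c}
        for name, m in table.items()
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def load_material_table(path: str | Path) -> dict[str, Material]:
    """Read a material table written by :func:`dump_material_table`."""
    payload = yaml.safe_load(Path(path).read_text())
    return {
        name: Material(name, d["density"], d["a_pe"], d["a_c"])
        for name, d in payload.items()
    }
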