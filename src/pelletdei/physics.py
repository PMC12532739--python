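"""Mass-attenuation physics for pellet materials.

Predicts theoretical Hounsfield units and dual-energy-index (DEI) values for
the five common shotgun-pellet metals (iron, copper, tungsten, lead, bismuth)
from tabulated elemental mass attenuation coefficients, with water standing in
for ballistic gelatine.  The monochromatic predictions explain *why* the DEI
separates low-Z from high-Z pellets: the energy dependence of mu/rho differs
strongly between Fe/Cu and the K-edge metals W/Pb/Bi.

Tables cover the diagnostically relevant 30-150 keV band and are shipped as
plain-text fixtures (``data/attenuation/``).  K absorption edges are stored as
two nodes 1 eV apart so interpolation stays well defined across the edge.

Note that these are single-energy (monochromatic) predictions.  A clinical
scanner integrates over a polychromatic spectrum and saturates for strongly
attenuating metals, so the *measured* DEI of W/Pb/Bi collapses far below the
monochromatic prediction; no attempt is made to model that here.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "AttenuationTable",
    "MaterialSpec",
    "EnergyRangeError",
    "material_library",
    "get_material",
    "mass_attenuation",
    "linear_attenuation",
    "hu_from_linear_attenuation",
    "hu_theoretical",
    "theoretical_dei",
]

PELLET_MATERIALS = ("iron", "copper", "tungsten", "lead", "bismuth")
WATER = "water"


class EnergyRangeError(ValueError):
    """Photon energy outside the tabulated range of a material."""


@dataclass(frozen=True)
class AttenuationTable:
    """Tabulated mass attenuation coefficient versus photon energy.

    Parameters
    ----------
    energies_kev : ndarray
        Strictly increasing photon energies, keV.
    mu_over_rho : ndarray
        Mass attenuation coefficients, cm^2/g, same length, all positive.
    """

    energies_kev: np.ndarray
    mu_over_rho: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_kev, dtype=float)
        m = np.asarray(self.mu_over_rho, dtype=float)
        if e.ndim != 1 or e.size < 2 or m.shape != e.shape:
            raise ValueError("table needs >= 2 matching (energy, mu/rho) rows")
        if not np.all(np.diff(e) > 0):
            raise ValueError("energies must be strictly increasing")
        if not (np.all(np.isfinite(e)) and np.all(np.isfinite(m)) and np.all(m > 0)):
            raise ValueError("mu/rho values must be finite and positive")
        object.__setattr__(self, "energies_kev", e)
        object.__setattr__(self, "mu_over_rho", m)

    @property
    def energy_range(self) -> tuple[float, float]:
        return float(self.energies_kev[0]), float(self.energies_kev[-1])


@dataclass(frozen=True)
class MaterialSpec:
    """A material with identity, bulk density and attenuation table."""

    name: str
    symbol: str
    atomic_number: int | None
    density_g_cm3: float
    table: AttenuationTable

    def __post_init__(self) -> None:
        if not self.density_g_cm3 > 0:
            raise ValueError("density must be positive")


def _read_table(text: str) -> AttenuationTable:
    rows = [
        line.split()
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    arr = np.array(rows, dtype=float)
    return AttenuationTable(arr[:, 0], arr[:, 1])


@lru_cache(maxsize=1)
def _load_library() -> tuple[Mapping[str, MaterialSpec], Mapping[str, str]]:
    root = resources.files("pelletdei").joinpath("data", "attenuation")
    manifest = yaml.safe_load(root.joinpath("manifest.yaml").read_text())
    materials = {}
    for key, entry in manifest["materials"].items():
        table = _read_table(root.joinpath(entry["table"]).read_text())
        z = entry["atomic_number"]
        materials[key] = MaterialSpec(
            name=entry["name"],
            symbol=entry["symbol"],
            atomic_number=None if z is None else int(z),
            density_g_cm3=float(entry["density_g_cm3"]),
            table=table,
        )
    return materials, dict(manifest.get("aliases", {}))


def material_library() -> Mapping[str, MaterialSpec]:
    """All packaged materials keyed by canonical name."""
    return dict(_load_library()[0])


def get_material(name: str) -> MaterialSpec:
    """Look up a packaged material by name, symbol or common alias.

    ``"steel"`` resolves to iron: steel shotgun pellets are soft iron and
    indistinguishable from it radiologically.
    """
    materials, aliases = _load_library()
    key = name.strip().lower()
    key = aliases.get(key, key)
    try:
        return materials[key]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; available: {sorted(materials)}"
        ) from None


def mass_attenuation(material: MaterialSpec, energy_kev) -> float | np.ndarray:
    """Interpolate mu/rho (cm^2/g) at the given photon energy (keV).

    Interpolation is linear in (log E, log mu/rho), the standard choice for
    attenuation tables which are near power-law between absorption edges.
    Energies that coincide with a table node return the tabulated value
    exactly.  Energies outside the tabulated range raise
    :class:`EnergyRangeError`.
    """
    e = np.asarray(energy_kev, dtype=float)
    t = material.table
    lo, hi = t.energy_range
    if np.any(e < lo) or np.any(e > hi):
        raise EnergyRangeError(
            f"energy out of range for {material.name}: "
            f"requested {energy_kev} keV, table covers [{lo}, {hi}] keV"
        )
    out = np.exp(np.interp(np.log(e), np.log(t.energies_kev), np.log(t.mu_over_rho)))
    # restore exact node values lost to the log/exp round trip
    idx = np.searchsorted(t.energies_kev, e)
    idx = np.clip(idx, 0, t.energies_kev.size - 1)
    at_node = t.energies_kev[idx] == e
    out = np.where(at_node, t.mu_over_rho[idx], out)
    return float(out) if np.isscalar(energy_kev) else out


def linear_attenuation(material: MaterialSpec, energy_kev) -> float | np.ndarray:
    """Linear attenuation coefficient mu = (mu/rho) * rho, 1/cm."""
    return mass_attenuation(material, energy_kev) * material.density_g_cm3


def hu_from_linear_attenuation(mu, mu_water) -> float | np.ndarray:
    """Hounsfield unit from linear attenuation: 1000 * (mu/mu_water - 1)."""
    return 1000.0 * (np.asarray(mu, dtype=float) / mu_water - 1.0)


def hu_theoretical(
    material: MaterialSpec, energy_kev, water: MaterialSpec | None = None
) -> float | np.ndarray:
    """Monochromatic HU of a material at the given energy.

    Uses the packaged water table as the reference.  Metals at diagnostic
    energies land far beyond the conventional 3071 HU ceiling; values are on
    the extended HU scale.
    """
    water = water if water is not None else get_material(WATER)
    mu_m = linear_attenuation(material, energy_kev)
    mu_w = linear_attenuation(water, energy_kev)
    out = hu_from_linear_attenuation(mu_m, mu_w)
    return float(out) if np.isscalar(energy_kev) else out


def theoretical_dei(
    material: MaterialSpec,
    e_low_kev: float,
    e_high_kev: float,
    water: MaterialSpec | None = None,
) -> float:
    """Monochromatic DEI prediction for a material at two photon energies.

    With r_i = mu_material(E_i) / mu_water(E_i), the DEI formula applied to
    the two theoretical HU values reduces algebraically to

        (r_low - r_high) / (r_low + r_high),

    because HU + 1000 = 1000 * r.  Water therefore has DEI 0 at every energy
    pair, and any material whose mu/mu_water ratio is energy independent does
    too.
    """
    if not e_low_kev < e_high_kev:
        raise ValueError("e_low must be strictly below e_high")
    water = water if water is not None else get_material(WATER)
    r_low = linear_attenuation(material, e_low_kev) / linear_attenuation(water, e_low_kev)
    r_high = linear_attenuation(material, e_high_kev) / linear_attenuation(
        water, e_high_kev
    )
    denom = r_low + r_high
    assert denom > 0, "attenuation ratios are positive by construction"
    return float((r_low - r_high) / denom)
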