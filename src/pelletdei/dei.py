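"""Dual-energy-index (DEI) computation on co-registered DECT volume pairs.

The DEI of a voxel with low- and high-kVp values I_low and I_high is

    DEI = (I_low - I_high) / (I_low + I_high + 2000),

a normalized spectral contrast that is zero for water (both HU equal 0) and
material specific otherwise.  The pair must be voxel-for-voxel co-registered,
as produced by a dual-source scanner or by the phantom generator; no
resampling is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "DEI_OFFSET_HU",
    "DualEnergyVolume",
    "DEIVolume",
    "dei_formula",
    "compute_dei_volume",
]

#: Offset in the DEI denominator; 2 * 1000 HU shifts both images back to a
#: linear-attenuation-proportional scale (HU + 1000).
DEI_OFFSET_HU = 2000.0


@dataclass
class DualEnergyVolume:
    """Co-registered low/high-kVp voxel grids in (extended) HU.

    Attributes
    ----------
    low_kv, high_kv : ndarray, 3D
        Reconstructed HU volumes at the low and high tube voltage.  The
        extended HU scale is permitted: metals may far exceed 3071 HU.
    spacing : (float, float, float)
        Voxel size in mm along each array axis.
    kvp_pair : (int, int) or None
        Tube voltages (low, high); None when unknown.
    meta : dict
        Free-form acquisition annotations.
    """

    low_kv: np.ndarray
    high_kv: np.ndarray
    spacing: tuple[float, float, float]
    kvp_pair: tuple[int, int] | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.low_kv = np.asarray(self.low_kv, dtype=np.float64)
        self.high_kv = np.asarray(self.high_kv, dtype=np.float64)
        if self.low_kv.ndim != 3 or self.high_kv.ndim != 3:
            raise ValueError("volumes must be 3-dimensional")
        if self.low_kv.shape != self.high_kv.shape:
            raise ValueError(
                f"shape mismatch: low {self.low_kv.shape} vs high {self.high_kv.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")
        if not (np.all(np.isfinite(self.low_kv)) and np.all(np.isfinite(self.high_kv))):
            raise ValueError("HU volumes contain non-finite values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.low_kv.shape


@dataclass
class DEIVolume:
    """Voxelwise DEI with a validity mask guarding the denominator."""

    dei: np.ndarray
    valid_mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.dei.shape != self.valid_mask.shape:
            raise ValueError("dei and valid_mask shapes differ")
        if not np.all(np.isfinite(self.dei[self.valid_mask])):
            raise ValueError("DEI must be finite on valid voxels")


def dei_formula(i_low, i_high):
    """Raw DEI arithmetic, elementwise; no denominator guard."""
    i_low = np.asarray(i_low, dtype=np.float64)
    i_high = np.asarray(i_high, dtype=np.float64)
    return (i_low - i_high) / (i_low + i_high + DEI_OFFSET_HU)


def compute_dei_volume(vol: DualEnergyVolume, guard_epsilon: float = 1.0) -> DEIVolume:
    """Compute the DEI volume for a co-registered dual-energy pair.

    Voxels whose denominator magnitude |I_low + I_high + 2000| falls below
    ``guard_epsilon`` (HU) are marked invalid and set to 0 rather than left
    non-finite, so downstream statistics never see NaN.  The degenerate case
    cannot occur for metal or gelatine voxels; the guard exists for synthetic
    or pathological inputs.
    """
    if guard_epsilon < 0:
        raise ValueError("guard_epsilon must be >= 0")
    denom = vol.low_kv + vol.high_kv + DEI_OFFSET_HU
    valid = np.abs(denom) >= guard_epsilon
    dei = np.zeros(vol.shape, dtype=np.float64)
    np.divide(vol.low_kv - vol.high_kv, denom, out=dei, where=valid)
    dei[~valid] = 0.0
    return DEIVolume(dei=dei, valid_mask=valid, spacing=vol.spacing)
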