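"""Synthetic dual-energy CT phantoms of pellet-bearing gelatine blocks.

The generator emulates the study geometry — 70 x 70 x 150 mm gelatine blocks
scanned at 0.504 x 0.504 x 1.0 mm voxels containing spherical metal pellets
of 3-4 mm diameter — and *calibrates* the pellet interiors so that the DEI
of each pellet reproduces a target per-material DEI distribution.  Given a
drawn pellet DEI d and a high-kVp interior anchor H2, the low-kVp interior

    H1 = (H2 * (1 + d) + 2000 * d) / (1 - d)

is the unique solution of d = (H1 - H2) / (H1 + H2 + 2000), so noise-free
interiors round-trip their drawn DEI exactly.

Realism modelled: partial-volume blending at pellet boundaries (supersampled
sphere rasterisation), additive Gaussian reconstruction noise independent at
the two energies, anisotropic voxels.  Not modelled: polychromatic spectra,
beam hardening and scatter, wound tracks, scanner blur.  An optional
subtractive streak artifact between high-Z pellet pairs is purely cosmetic.

Every block carries a ground-truth sidecar (per-pellet centre, diameter,
material, drawn DEI, interior HU pair) so each pipeline stage is testable
without any external data.  Random draws come from one seeded generator per
block in a documented order: per-pellet DEI (and anchor jitter), then noise;
pellet centres are drawn when the block layout is built.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Any, Mapping

import numpy as np
import yaml

from .dei import DualEnergyVolume

__all__ = [
    "MaterialHUProfile",
    "Pellet",
    "PhantomSpec",
    "PelletOverlapWarning",
    "load_profiles",
    "profile_names",
    "invert_dei",
    "build_calibration",
    "sphere_fractions",
    "generate_block",
    "default_phantom",
]

#: Denominator offset of the DEI formula, HU.
_DEI_OFFSET = 2000.0


class PelletOverlapWarning(UserWarning):
    """Two pellets overlap; their components will merge in the truth."""


@dataclass(frozen=True)
class MaterialHUProfile:
    """Two-energy HU recipe for one pellet material.

    ``dei_mean``/``dei_sd`` define the per-pellet DEI distribution the
    generated pellets reproduce; ``hu_high_anchor`` is the interior high-kVp
    HU (well above the 2000 HU segmentation threshold, on the extended
    scale).  ``per_pellet_hu_jitter`` optionally perturbs the anchor per
    pellet (the drawn DEI is preserved because the low-kVp value is derived
    from the jittered anchor).
    """

    material: str
    dei_mean: float
    dei_sd: float
    hu_high_anchor: float = 8000.0
    per_pellet_hu_jitter: float = 0.0

    def __post_init__(self) -> None:
        if not abs(self.dei_mean) < 1:
            raise ValueError("|dei_mean| must be < 1")
        if self.dei_sd < 0:
            raise ValueError("dei_sd must be >= 0")
        if not self.hu_high_anchor > 2000.0:
            raise ValueError("hu_high_anchor must exceed the 2000 HU threshold")


@dataclass(frozen=True)
class Pellet:
    center_mm: tuple[float, float, float]
    diameter_mm: float
    material: str

    def __post_init__(self) -> None:
        if not self.diameter_mm > 0:
            raise ValueError("pellet diameter must be positive")


@dataclass
class PhantomSpec:
    """Layout and acquisition parameters of one synthetic gelatine block."""

    pellets: list[Pellet] = field(default_factory=list)
    block_size_mm: tuple[float, float, float] = (70.0, 70.0, 150.0)
    spacing_mm: tuple[float, float, float] = (0.504, 0.504, 1.0)
    gelatine_hu: tuple[float, float] = (60.0, 50.0)
    noise_sd: float = 15.0
    supersample: int = 4
    seed: int = 0
    kvp_pair: tuple[int, int] = (100, 140)
    name: str = "block"
    #: cosmetic streak-artifact depth in HU (0 disables). Subtracts a dark
    #: band along each pellet-pair axis, visually imitating beam-hardening
    #: streaks between dense objects. NOT a physics simulation.
    streak_amplitude_hu: float = 0.0

    def __post_init__(self) -> None:
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for p in self.pellets:
            r = p.diameter_mm / 2.0
            for c, size in zip(p.center_mm, self.block_size_mm):
                if c - r < 0 or c + r > size:
                    raise ValueError(f"pellet at {p.center_mm} extends outside block")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(
            int(round(s / d)) for s, d in zip(self.block_size_mm, self.spacing_mm)
        )


def _profiles_path():
    return resources.files("pelletdei").joinpath("data", "profiles.yaml")


@lru_cache(maxsize=1)
def _load_profiles_yaml() -> dict:
    return yaml.safe_load(_profiles_path().read_text())


def profile_names() -> list[str]:
    return sorted(_load_profiles_yaml())


def load_profiles(name: str) -> dict[str, Any]:
    """Raw configuration of a packaged phantom profile."""
    cfg = _load_profiles_yaml()
    if name not in cfg:
        raise KeyError(f"unknown phantom profile {name!r}; available: {sorted(cfg)}")
    return cfg[name]


def invert_dei(dei: float, hu_high: float) -> float:
    """Low-kVp HU that yields the target DEI at the given high-kVp HU.

    Solves dei = (H1 - H2) / (H1 + H2 + 2000) for H1.  A |dei| >= 1 has no
    finite solution.
    """
    if not abs(dei) < 1:
        raise ValueError(f"no finite low-kVp HU for |DEI| >= 1 (got {dei})")
    return (hu_high * (1.0 + dei) + _DEI_OFFSET * dei) / (1.0 - dei)


def build_calibration(
    dei_stats: Mapping[str, tuple[float, float]],
    hu_high_anchor: float = 8000.0,
) -> dict[str, MaterialHUProfile]:
    """Material HU profiles from per-material (DEI mean, DEI SD) statistics."""
    return {
        m: MaterialHUProfile(
            material=m, dei_mean=float(mean), dei_sd=float(sd), hu_high_anchor=hu_high_anchor
        )
        for m, (mean, sd) in dei_stats.items()
    }


def _calibration_from_profile(cfg: dict) -> dict[str, MaterialHUProfile]:
    anchor = float(cfg.get("hu_high_anchor", 8000.0))
    return build_calibration(
        {m: (e["dei_mean"], e["dei_sd"]) for m, e in cfg["materials"].items()},
        hu_high_anchor=anchor,
    )


def sphere_fractions(
    center_mm: tuple[float, float, float],
    diameter_mm: float,
    spacing_mm: tuple[float, float, float],
    shape: tuple[int, int, int],
    supersample: int,
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Per-voxel volume fraction occupied by a sphere, over its bounding box.

    Voxel i spans [i*dx, (i+1)*dx) along each axis.  Each voxel in the
    sphere's bounding box is subdivided ``supersample`` times per axis and
    the fraction of sub-voxel centres inside the sphere is returned.
    """
    r = diameter_mm / 2.0
    spacing = np.asarray(spacing_mm, dtype=float)
    center = np.asarray(center_mm, dtype=float)
    lo = np.maximum(np.floor((center - r) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((center + r) / spacing).astype(int), np.asarray(shape))
    box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    s = supersample
    axes = []
    for ax in range(3):
        edges = np.arange(lo[ax], hi[ax], dtype=float)
        sub = (np.arange(s) + 0.5) / s
        coords = (edges[:, None] + sub[None, :]).ravel() * spacing[ax] - center[ax]
        axes.append(coords)
    dx2 = axes[0][:, None, None] ** 2
    dy2 = axes[1][None, :, None] ** 2
    dz2 = axes[2][None, None, :] ** 2
    inside = (dx2 + dy2 + dz2) <= r * r
    n = tuple(hi - lo)
    frac = (
        inside.reshape(n[0], s, n[1], s, n[2], s)
        .mean(axis=(1, 3, 5))
        .astype(np.float64)
    )
    return box, frac


def generate_block(
    spec: PhantomSpec, profiles: Mapping[str, MaterialHUProfile]
) -> tuple[DualEnergyVolume, dict[str, Any]]:
    """Rasterise one gelatine block into a dual-energy volume pair.

    Each voxel's HU is the partial-volume blend f*H_material + (1-f)*H_gel,
    independently at the two energies, plus additive Gaussian noise.  The
    same spec and seed always produce bit-identical volumes.  Returns the
    volume and a ground-truth sidecar (dict, JSON-serialisable).
    """
    for p in spec.pellets:
        if p.material not in profiles:
            raise KeyError(f"no HU profile for material {p.material!r}")
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    gel_low, gel_high = (float(h) for h in spec.gelatine_hu)
    low = np.full(shape, gel_low, dtype=np.float64)
    high = np.full(shape, gel_high, dtype=np.float64)

    # overlap check (pairwise centre distance below the sum of radii)
    merged = [False] * len(spec.pellets)
    for i in range(len(spec.pellets)):
        for j in range(i + 1, len(spec.pellets)):
            a, b = spec.pellets[i], spec.pellets[j]
            dist = float(
                np.linalg.norm(np.subtract(a.center_mm, b.center_mm))
            )
            if dist < (a.diameter_mm + b.diameter_mm) / 2.0:
                merged[i] = merged[j] = True
                warnings.warn(
                    f"pellets {i} and {j} overlap (centres {dist:.2f} mm apart); "
                    "their components will merge",
                    PelletOverlapWarning,
                    stacklevel=2,
                )

    truth_pellets = []
    for i, p in enumerate(spec.pellets):
        prof = profiles[p.material]
        d = float(rng.normal(prof.dei_mean, prof.dei_sd)) if prof.dei_sd > 0 else prof.dei_mean
        h2 = prof.hu_high_anchor
        if prof.per_pellet_hu_jitter > 0:
            h2 += float(rng.normal(0.0, prof.per_pellet_hu_jitter))
        h1 = invert_dei(d, h2)
        box, frac = sphere_fractions(
            p.center_mm, p.diameter_mm, spec.spacing_mm, shape, spec.supersample
        )
        low[box] = frac * h1 + (1.0 - frac) * low[box]
        high[box] = frac * h2 + (1.0 - frac) * high[box]
        truth_pellets.append(
            {
                "index": i,
                "center_mm": [float(c) for c in p.center_mm],
                "diameter_mm": float(p.diameter_mm),
                "material": p.material,
                "dei": d,
                "hu_low": float(h1),
                "hu_high": float(h2),
                "merged": merged[i],
            }
        )

    if spec.streak_amplitude_hu > 0 and len(spec.pellets) >= 2:
        _apply_streaks(low, high, spec)

    if spec.noise_sd > 0:
        low += rng.normal(0.0, spec.noise_sd, size=shape)
        high += rng.normal(0.0, spec.noise_sd, size=shape)

    vol = DualEnergyVolume(
        low_kv=low,
        high_kv=high,
        spacing=spec.spacing_mm,
        kvp_pair=spec.kvp_pair,
        meta={"name": spec.name, "synthetic": True, "seed": int(spec.seed)},
    )
    truth = {
        "name": spec.name,
        "seed": int(spec.seed),
        "kvp_pair": list(spec.kvp_pair),
        "block_size_mm": list(spec.block_size_mm),
        "spacing_mm": list(spec.spacing_mm),
        "gelatine_hu": list(spec.gelatine_hu),
        "noise_sd": float(spec.noise_sd),
        "supersample": int(spec.supersample),
        "pellets": truth_pellets,
    }
    return vol, truth


def _apply_streaks(low: np.ndarray, high: np.ndarray, spec: PhantomSpec) -> None:
    """Subtract a dark band along each pellet-pair axis (cosmetic only).

    A crude visual stand-in for the beam-hardening streaks seen between
    dense objects; amplitude decays with distance from the connecting
    segment.  Deliberately not a physics model — off by default.
    """
    spacing = np.asarray(spec.spacing_mm)
    grids = np.meshgrid(
        *[(np.arange(n) + 0.5) * s for n, s in zip(spec.shape, spacing)],
        indexing="ij",
    )
    pts = np.stack(grids, axis=-1)  # (nx, ny, nz, 3) voxel centres, mm
    sigma = 1.5  # band half-width, mm
    for i in range(len(spec.pellets)):
        for j in range(i + 1, len(spec.pellets)):
            a = np.asarray(spec.pellets[i].center_mm)
            b = np.asarray(spec.pellets[j].center_mm)
            ab = b - a
            t = np.clip(((pts - a) @ ab) / (ab @ ab), 0.0, 1.0)
            dist = np.linalg.norm(pts - (a + t[..., None] * ab), axis=-1)
            band = spec.streak_amplitude_hu * np.exp(-0.5 * (dist / sigma) ** 2)
            low -= band
            high -= band


def sample_centers(
    rng: np.random.Generator,
    n: int,
    block_size_mm: tuple[float, float, float],
    diameter_mm: float,
    depth_range_mm: tuple[float, float] = (20.0, 120.0),
    min_separation_mm: float = 10.0,
    margin_mm: float = 3.0,
    max_attempts: int = 100_000,
) -> list[tuple[float, float, float]]:
    """Uniform random pellet centres with a minimum pairwise separation.

    In-plane positions are uniform inside the block minus a safety margin;
    axial depth is uniform in ``depth_range_mm`` (the band pellets come to
    rest in after penetrating the entrance face).  Rejection sampling.
    """
    lo_margin = diameter_mm / 2.0 + margin_mm
    centers: list[np.ndarray] = []
    for _ in range(max_attempts):
        if len(centers) == n:
            break
        cand = np.array(
            [
                rng.uniform(lo_margin, block_size_mm[0] - lo_margin),
                rng.uniform(lo_margin, block_size_mm[1] - lo_margin),
                rng.uniform(*depth_range_mm),
            ]
        )
        if all(np.linalg.norm(cand - c) >= min_separation_mm for c in centers):
            centers.append(cand)
    if len(centers) < n:
        raise RuntimeError("could not place all pellets at the requested separation")
    return [tuple(float(x) for x in c) for c in centers]


def default_phantom(
    profile_name: str, seed: int = 0
) -> tuple[list[PhantomSpec], dict[str, MaterialHUProfile]]:
    """Block layouts and calibration for a packaged study profile.

    ``"paper-100-140"`` yields five blocks, one per material, with the
    study's pellet counts (steel 5, lead 4, copper 13, tungsten 6,
    bismuth 8), 3 mm diameters and seeded random centres 20-120 mm deep with
    >= 10 mm pairwise separation.  ``"paper-80-140-steel"`` yields two
    20-pellet steel blocks of 3 mm and 4 mm diameter.

    Per-block seeds are derived from ``seed`` and the block index, so block
    contents are independent but fully reproducible.
    """
    cfg = load_profiles(profile_name)
    calibration = _calibration_from_profile(cfg)
    block_size = tuple(float(v) for v in cfg["block_size_mm"])
    spacing = tuple(float(v) for v in cfg["spacing_mm"])
    depth = tuple(float(v) for v in cfg["depth_range_mm"])
    min_sep = float(cfg["min_separation_mm"])
    kvp = tuple(int(v) for v in cfg["kvp"])
    specs = []
    for idx, (material, entry) in enumerate(cfg["materials"].items()):
        n = int(entry["n_pellets"])
        diameter = float(entry.get("diameter_mm", 3.0))
        center_rng = np.random.default_rng(np.random.SeedSequence([seed, idx, 0]))
        centers = sample_centers(
            center_rng, n, block_size, diameter,
            depth_range_mm=depth, min_separation_mm=min_sep,
        )
        block_seed = int(
            np.random.SeedSequence([seed, idx, 1]).generate_state(1)[0] % (2**31)
        )
        specs.append(
            PhantomSpec(
                pellets=[Pellet(c, diameter, material) for c in centers],
                block_size_mm=block_size,
                spacing_mm=spacing,
                gelatine_hu=tuple(float(v) for v in cfg["gelatine_hu"]),
                noise_sd=float(cfg["noise_sd"]),
                seed=block_seed,
                kvp_pair=kvp,
                name=f"{profile_name}-{material}",
            )
        )
    return specs, calibration
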