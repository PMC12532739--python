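"""NIfTI / JSON / CSV readers and writers for the pipeline artifacts.

Volumes travel as NIfTI with voxel spacing in the header and an optional
JSON sidecar carrying the kVp pair (and, if the header cannot be trusted, a
spacing override).  Per-pellet records are written as plain CSV with DEI at
six decimals, preceded by one comment line carrying the configuration hash
and seed so a result file identifies the run that produced it.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .dei import DualEnergyVolume
from .segment import PelletRecord

__all__ = [
    "read_volume",
    "write_volume",
    "write_dual_energy",
    "read_dual_energy",
    "records_to_frame",
    "write_records_csv",
    "read_records_csv",
]

log = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "label",
    "voxel_count",
    "centroid_x_mm",
    "centroid_y_mm",
    "centroid_z_mm",
    "mean_dei",
    "sd_dei",
    "mean_hu_high",
]


def write_volume(path, data: np.ndarray, spacing) -> None:
    """Write a 3D array as NIfTI with the given voxel spacing (mm)."""
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(tuple(float(s) for s in spacing))
    nib.save(img, str(path))


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume; returns (array, spacing_mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def write_dual_energy(outdir, vol: DualEnergyVolume, prefix: str = "block", truth=None):
    """Write a dual-energy pair plus JSON sidecar (and optional truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    low = outdir / f"{prefix}_low.nii.gz"
    high = outdir / f"{prefix}_high.nii.gz"
    write_volume(low, vol.low_kv, vol.spacing)
    write_volume(high, vol.high_kv, vol.spacing)
    sidecar = {
        "kvp_pair": list(vol.kvp_pair) if vol.kvp_pair else None,
        "spacing_mm": list(vol.spacing),
        "meta": vol.meta,
    }
    sidecar_path = outdir / f"{prefix}_sidecar.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    if truth is not None:
        (outdir / f"{prefix}_truth.json").write_text(
            json.dumps(truth, indent=2, sort_keys=True)
        )
    return low, high, sidecar_path


def read_dual_energy(low_path, high_path, sidecar_path=None) -> DualEnergyVolume:
    """Read a co-registered dual-energy pair.

    Spacing comes from the NIfTI headers; if the sidecar carries a
    ``spacing_mm`` override it wins, with a logged warning.  A header
    spacing disagreement between the two volumes beyond 1e-4 mm, or a shape
    mismatch, is an error.  A missing kVp pair is only a warning.
    """
    low, sp_low = read_volume(low_path)
    high, sp_high = read_volume(high_path)
    if low.shape != high.shape:
        raise ValueError(
            f"shape mismatch: {low_path} {low.shape} vs {high_path} {high.shape}"
        )
    if any(abs(a - b) > 1e-4 for a, b in zip(sp_low, sp_high)):
        raise ValueError(f"header spacing mismatch: {sp_low} vs {sp_high}")
    spacing = sp_low
    kvp = None
    meta = {}
    if sidecar_path is not None:
        sidecar = json.loads(Path(sidecar_path).read_text())
        meta = sidecar.get("meta", {})
        if sidecar.get("spacing_mm") is not None:
            override = tuple(float(s) for s in sidecar["spacing_mm"])
            if any(abs(a - b) > 1e-4 for a, b in zip(override, spacing)):
                log.warning(
                    "sidecar spacing %s overrides header spacing %s", override, spacing
                )
            spacing = override
        if sidecar.get("kvp_pair"):
            kvp = tuple(int(v) for v in sidecar["kvp_pair"])
    if kvp is None:
        log.warning("kVp pair unknown (no sidecar entry); recording as None")
    return DualEnergyVolume(low_kv=low, high_kv=high, spacing=spacing, kvp_pair=kvp, meta=meta)


def records_to_frame(
    records: list[PelletRecord], material: str | None = None, block: str | None = None
) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "label": r.label,
            "voxel_count": r.voxel_count,
            "centroid_x_mm": r.centroid_mm[0],
            "centroid_y_mm": r.centroid_mm[1],
            "centroid_z_mm": r.centroid_mm[2],
            "mean_dei": r.mean_dei,
            "sd_dei": r.sd_dei,
            "mean_hu_high": r.mean_hu_high,
        }
        if block is not None:
            row["block"] = block
        if material is not None:
            row["material"] = material
        rows.append(row)
    cols = RECORD_COLUMNS + (["block"] if block is not None else []) + (
        ["material"] if material is not None else []
    )
    return pd.DataFrame(rows, columns=cols)


def _format_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in ("centroid_x_mm", "centroid_y_mm", "centroid_z_mm"):
        if col in df:
            df[col] = df[col].map(lambda v: f"{v:.3f}")
    for col in ("mean_dei", "sd_dei"):
        if col in df:
            df[col] = df[col].map(lambda v: f"{v:.6f}")
    if "mean_hu_high" in df:
        df["mean_hu_high"] = df["mean_hu_high"].map(lambda v: f"{v:.1f}")
    return df


def write_records_csv(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write per-pellet records as CSV (UTF-8, '.' decimal, DEI at 6 dp)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    text = _format_frame(df).to_csv(index=False, lineterminator="\n")
    if header_comment:
        text = f"# {header_comment}\n" + text
    path.write_text(text, encoding="utf-8")


def read_records_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
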