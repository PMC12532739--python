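from __future__ import annotations

import numpy as np
import pytest

from pelletdei import (
    MaterialHUProfile,
    Pellet,
    PhantomSpec,
    build_calibration,
    compute_dei_volume,
    generate_block,
    segment_pellets,
)


@pytest.fixture
def steel_calibration() -> dict[str, MaterialHUProfile]:
    return build_calibration({"steel": (0.212, 0.006)})


@pytest.fixture
def small_block_factory(steel_calibration):
    """Factory for compact single-material test blocks.

    Pellets sit on a fixed well-separated grid inside a 40 mm cube so the
    block generates in milliseconds.
    """

    def make(
        n_pellets: int = 3,
        diameter: float = 3.0,
        noise_sd: float = 15.0,
        seed: int = 0,
        material: str = "steel",
        calibration=None,
    ):
        positions = [
            (12.0, 12.0, 12.0),
            (28.0, 12.0, 14.0),
            (12.0, 28.0, 18.0),
            (28.0, 28.0, 24.0),
            (20.0, 20.0, 30.0),
        ]
        spec = PhantomSpec(
            pellets=[Pellet(p, diameter, material) for p in positions[:n_pellets]],
            block_size_mm=(40.0, 40.0, 40.0),
            noise_sd=noise_sd,
            seed=seed,
        )
        cal = calibration if calibration is not None else steel_calibration
        return spec, generate_block(spec, cal)

    return make


@pytest.fixture
def run_block():
    """Run DEI + segmentation on a generated block, returning the records."""

    def run(vol, **seg_kwargs):
        from pelletdei import SegmentationConfig

        dei = compute_dei_volume(vol)
        cfg = SegmentationConfig(**seg_kwargs) if seg_kwargs else None
        _, records = segment_pellets(vol.high_kv, dei, cfg)
        return records

    return run
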