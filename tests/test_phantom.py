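"""Synthetic phantom generator: calibration inversion, rasterisation, truth."""

import numpy as np
import pytest

from pelletdei import (
    MaterialHUProfile,
    Pellet,
    PhantomSpec,
    build_calibration,
    compute_dei_volume,
    dei_formula,
    default_phantom,
    generate_block,
    invert_dei,
)
from pelletdei.phantom import PelletOverlapWarning, sphere_fractions


class TestCalibrationInversion:
    def test_zero_dei_is_a_fixed_point(self):
        assert invert_dei(0.0, 8000.0) == pytest.approx(8000.0)

    def test_algebraic_roundtrip_through_the_dei_formula(self):
        h1 = invert_dei(0.212, 8000.0)
        assert h1 == pytest.approx(12842.64, abs=0.01)
        assert dei_formula(h1, 8000.0) == pytest.approx(0.212, abs=1e-12)
        for d in (-0.5, 0.008, 0.3, 0.9):
            assert dei_formula(invert_dei(d, 8000.0), 8000.0) == pytest.approx(d, abs=1e-12)

    def test_unit_dei_has_no_finite_solution(self):
        with pytest.raises(ValueError):
            invert_dei(1.0, 8000.0)

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            MaterialHUProfile("x", dei_mean=1.2, dei_sd=0.0)
        with pytest.raises(ValueError):
            MaterialHUProfile("x", dei_mean=0.1, dei_sd=0.0, hu_high_anchor=1500.0)


class TestSphereRasterisation:
    @pytest.mark.parametrize("diameter", [3.0, 4.0])
    def test_partial_volume_fractions_integrate_to_sphere_volume(self, diameter):
        spacing = (0.504, 0.504, 1.0)
        box, frac = sphere_fractions(
            (10.1, 9.87, 10.33), diameter, spacing, (40, 40, 20), supersample=4
        )
        measured = frac.sum() * np.prod(spacing)
        analytic = np.pi / 6 * diameter**3
        assert measured == pytest.approx(analytic, rel=0.02)

    def test_fractions_bounded_and_interior_full(self):
        box, frac = sphere_fractions((10.0, 10.0, 10.0), 4.0, (0.5, 0.5, 0.5), (40, 40, 40), 4)
        assert frac.min() >= 0.0 and frac.max() <= 1.0
        assert frac.max() == 1.0  # a 4 mm sphere contains whole 0.5 mm voxels


class TestGenerateBlock:
    def test_empty_noise_free_block_is_constant_gelatine(self, steel_calibration):
        spec = PhantomSpec(pellets=[], block_size_mm=(10, 10, 10), noise_sd=0.0)
        vol, truth = generate_block(spec, steel_calibration)
        assert np.all(vol.low_kv == 60.0) and np.all(vol.high_kv == 50.0)
        assert truth["pellets"] == []

    def test_same_seed_is_bit_identical(self, small_block_factory):
        _, (vol_a, truth_a) = small_block_factory(seed=7)
        _, (vol_b, truth_b) = small_block_factory(seed=7)
        np.testing.assert_array_equal(vol_a.low_kv, vol_b.low_kv)
        np.testing.assert_array_equal(vol_a.high_kv, vol_b.high_kv)
        assert truth_a == truth_b

    def test_noise_free_interior_reproduces_drawn_dei_exactly(self, small_block_factory):
        spec, (vol, truth) = small_block_factory(n_pellets=1, noise_sd=0.0)
        p = truth["pellets"][0]
        # centre voxel is fully interior: its DEI is the drawn DEI
        idx = tuple(int(c / s) for c, s in zip(p["center_mm"], spec.spacing_mm))
        dei = compute_dei_volume(vol)
        assert dei.dei[idx] == pytest.approx(p["dei"], abs=1e-12)

    def test_boundary_voxels_biased_toward_gelatine(self, small_block_factory):
        spec, (vol, truth) = small_block_factory(n_pellets=1, noise_sd=0.0)
        p = truth["pellets"][0]
        dei = compute_dei_volume(vol).dei
        interior = p["dei"]
        # voxels with partial fill have DEI strictly between background and interior
        partial = (vol.high_kv > 100) & (vol.high_kv < 0.95 * p["hu_high"])
        assert partial.any()
        background = dei_formula(60.0, 50.0)
        assert np.all(dei[partial] < interior)
        assert np.all(dei[partial] > background - 1e-9)

    def test_overlapping_pellets_warn_and_mark_merge(self, steel_calibration):
        spec = PhantomSpec(
            pellets=[
                Pellet((10.0, 10.0, 10.0), 3.0, "steel"),
                Pellet((12.0, 10.0, 10.0), 3.0, "steel"),
            ],
            block_size_mm=(20, 20, 20),
            noise_sd=0.0,
        )
        with pytest.warns(PelletOverlapWarning):
            _, truth = generate_block(spec, steel_calibration)
        assert all(p["merged"] for p in truth["pellets"])

    def test_pellet_outside_block_is_an_error(self):
        with pytest.raises(ValueError, match="outside"):
            PhantomSpec(pellets=[Pellet((1.0, 10.0, 10.0), 3.0, "steel")],
                        block_size_mm=(20, 20, 20))

    def test_missing_profile_is_an_error(self, steel_calibration):
        spec = PhantomSpec(pellets=[Pellet((10.0, 10.0, 10.0), 3.0, "lead")],
                           block_size_mm=(20, 20, 20))
        with pytest.raises(KeyError):
            generate_block(spec, steel_calibration)


class TestDefaultPhantom:
    def test_study_profile_has_printed_pellet_counts(self):
        specs, calibration = default_phantom("paper-100-140", seed=3)
        counts = {s.pellets[0].material: len(s.pellets) for s in specs}
        assert counts == {"steel": 5, "lead": 4, "copper": 13, "tungsten": 6, "bismuth": 8}
        assert sum(counts.values()) == 36
        assert set(calibration) == set(counts)
        for s in specs:
            assert s.shape == (139, 139, 150)
            depths = [p.center_mm[2] for p in s.pellets]
            assert min(depths) >= 20.0 and max(depths) <= 120.0
            centers = np.array([p.center_mm for p in s.pellets])
            for i in range(len(centers)):
                for j in range(i + 1, len(centers)):
                    assert np.linalg.norm(centers[i] - centers[j]) >= 10.0

    def test_size_robustness_profile(self):
        specs, _ = default_phantom("paper-80-140-steel", seed=3)
        assert [len(s.pellets) for s in specs] == [20, 20]
        assert sorted({p.diameter_mm for s in specs for p in s.pellets}) == [3.0, 4.0]
        assert all(s.kvp_pair == (80, 140) for s in specs)

    def test_unknown_profile_name(self):
        with pytest.raises(KeyError):
            default_phantom("no-such-profile")


class TestBuildCalibration:
    def test_profiles_from_stats(self):
        cal = build_calibration({"steel": (0.212, 0.006), "lead": (0.008, 0.001)})
        assert cal["steel"].dei_mean == 0.212
        assert cal["lead"].hu_high_anchor == 8000.0
        with pytest.raises(ValueError):
            build_calibration({"bad": (1.0, 0.0)})


class TestStreakOverlay:
    def test_streaks_darken_the_line_between_pellets_and_default_off(self, steel_calibration):
        pellets = [Pellet((8.0, 10.0, 10.0), 3.0, "steel"),
                   Pellet((24.0, 10.0, 10.0), 3.0, "steel")]
        base = PhantomSpec(pellets=pellets, block_size_mm=(32, 20, 20), noise_sd=0.0)
        streaked = PhantomSpec(pellets=pellets, block_size_mm=(32, 20, 20),
                               noise_sd=0.0, streak_amplitude_hu=200.0)
        vol0, _ = generate_block(base, steel_calibration)
        vol1, _ = generate_block(streaked, steel_calibration)
        mid = tuple(int(c / s) for c, s in zip((16.0, 10.0, 10.0), base.spacing_mm))
        assert vol1.high_kv[mid] < vol0.high_kv[mid] - 100
        # far corner untouched within float noise
        assert vol1.high_kv[2, 2, 2] == pytest.approx(vol0.high_kv[2, 2, 2], abs=1.0)
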