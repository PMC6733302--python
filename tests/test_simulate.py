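"""Synthetic-data generator: density fields, dosing, scans, weights."""

import numpy as np
import pytest

from thzpowder import (
    DensityField,
    DosingEvent,
    ScanConfig,
    apply_dosing,
    compute_reflection_series,
    fresnel_reflection,
    index_from_density,
    invert_reflection,
    make_density_field,
    synthesize_fill_weights,
    synthesize_scan,
)
from thzpowder.signal import peak_amplitudes


def uniform_field(rho: float, n_cells: int = 360, stage: int = 0) -> DensityField:
    return DensityField(np.arange(n_cells) * 360.0 / n_cells,
                        np.full(n_cells, rho), stage_label=stage)


class TestMakeDensityField:
    def test_zero_pressure_baseline_is_bulk_ratio(self, material, geometry):
        (f,) = make_density_field(material, geometry, stage_pressures=[0.0],
                                  heterogeneity_amp=0.0, seed=0)
        assert np.allclose(f.relative_density,
                           material.bulk_density / material.true_density)

    def test_lactohale100_flat_field_value(self, geometry):
        from thzpowder import LACTOHALE_100

        (f,) = make_density_field(LACTOHALE_100, geometry,
                                  stage_pressures=[0.0],
                                  heterogeneity_amp=0.0, seed=0)
        assert f.relative_density[0] == pytest.approx(0.697 / 1.539)
        assert np.ptp(f.relative_density) == 0.0  # zero angular variance

    def test_stage_means_increase_with_pressure(self, lh200, geometry):
        fields = make_density_field(lh200, geometry,
                                    stage_pressures=[0.0, 2.0, 4.0, 6.0, 8.0],
                                    heterogeneity_amp=0.01, seed=1)
        means = [f.mean for f in fields]
        assert np.all(np.diff(means) > 0)

    def test_heterogeneity_amplitude_respected(self, lh200, geometry):
        (f,) = make_density_field(lh200, geometry, stage_pressures=[0.0],
                                  heterogeneity_amp=0.02, seed=2)
        dev = f.relative_density - f.relative_density.mean()
        assert np.max(np.abs(dev)) == pytest.approx(0.02, rel=0.2)

    def test_excessive_amplitude_rejected(self, lh200, geometry):
        with pytest.raises(ValueError):
            make_density_field(lh200, geometry, stage_pressures=[0.0],
                               heterogeneity_amp=0.7, seed=0)

    def test_decreasing_pressures_rejected(self, lh200, geometry):
        with pytest.raises(ValueError):
            make_density_field(lh200, geometry, stage_pressures=[4.0, 2.0])

    def test_seed_reproducibility(self, lh200, geometry):
        a = make_density_field(lh200, geometry, seed=7)
        b = make_density_field(lh200, geometry, seed=7)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.relative_density, fb.relative_density)


class TestApplyDosing:
    def test_zero_deficit_is_identity(self):
        f = uniform_field(0.5)
        out = apply_dosing(f, DosingEvent(hole_density_deficit=0.0))
        assert np.array_equal(out.relative_density, f.relative_density)
        assert out is not f

    def test_eight_depressed_segments(self):
        f = uniform_field(0.5, n_cells=720)
        out = apply_dosing(f, DosingEvent(hole_density_deficit=0.1,
                                          hole_width=4.0))
        below = out.relative_density < f.relative_density.min()
        # count contiguous runs (circular)
        transitions = np.sum(below & ~np.roll(below, 1))
        assert transitions == 8
        assert np.allclose(out.relative_density[below], 0.45)
        assert np.allclose(out.relative_density[~below], 0.5)

    def test_wrap_around_hole_depresses_both_edges(self):
        f = uniform_field(0.5, n_cells=360)
        positions = np.array([0.0, 45, 90, 135, 180, 225, 270, 315])
        out = apply_dosing(f, DosingEvent(positions=positions,
                                          hole_density_deficit=0.1,
                                          hole_width=20.0))
        # hole centred at 0 deg spans 350..10: both edge cells depressed
        assert out.relative_density[355] < 0.5
        assert out.relative_density[5] < 0.5
        assert out.relative_density[15] == 0.5

    def test_overlapping_holes_rejected(self):
        f = uniform_field(0.5)
        ev = DosingEvent(positions=np.array([0, 30, 90, 135, 180, 225, 270,
                                             315]),
                         hole_width=61.0)
        with pytest.raises(ValueError, match="overlap"):
            apply_dosing(f, ev)


class TestSynthesizeScan:
    def test_constant_field_constant_amplitudes(self, lh200, geometry,
                                                locked_scan_config):
        f = uniform_field(0.45)
        scan, ref = synthesize_scan(f, lh200, geometry, locked_scan_config)
        peaks = peak_amplitudes(scan)
        on_datum = geometry.in_datum(locked_scan_config.measurement_angles())
        assert np.allclose(peaks[~on_datum], peaks[~on_datum][0], atol=1e-15)
        assert np.ptp(peaks[~on_datum]) == pytest.approx(0.0, abs=1e-15)

    def test_noiseless_round_trip_recovers_index(self, lh200, geometry,
                                                 locked_scan_config):
        fields = make_density_field(lh200, geometry, heterogeneity_amp=0.02,
                                    seed=5, n_cells=225)
        f = fields[0]
        scan, ref = synthesize_scan(f, lh200, geometry, locked_scan_config)
        series = compute_reflection_series(scan, ref)
        theta = locked_scan_config.measurement_angles()
        on_datum = geometry.in_datum(theta)
        n_p = invert_reflection(series.r[~on_datum], geometry.container_index)
        expected = index_from_density(f.density_at(theta[~on_datum]),
                                      lh200.solid_refractive_index)
        assert np.max(np.abs(n_p - expected)) < 1e-10

    def test_angular_coverage_of_nominal_acquisition(self):
        cfg = ScanConfig(n_waveforms=2000, acquisition_rate=15.0,
                         rotation_speed=4.0)
        # nominal arithmetic: 133.3 s at 4 rpm covers 8.89 rotations
        assert 8.0 < cfg.rotations_covered < 9.0
        assert cfg.rotations_covered == pytest.approx(2000 / 15 * 4 / 60)

    def test_datum_opposes_powder_reflection_sign(self, lh200, geometry,
                                                  locked_scan_config):
        f = uniform_field(0.45)
        scan, ref = synthesize_scan(f, lh200, geometry, locked_scan_config)
        series = compute_reflection_series(scan, ref)
        on_datum = geometry.in_datum(locked_scan_config.measurement_angles())
        assert np.all(series.r[on_datum] == -1.0)
        assert np.all(series.r[~on_datum] > 0)  # n_p < n_c regime

    def test_seed_reproducibility_bit_identical(self, lh200, geometry):
        f = uniform_field(0.45)
        cfg = ScanConfig(noise_sigma=0.0015, seed=11, n_waveforms=300)
        s1, _ = synthesize_scan(f, lh200, geometry, cfg)
        s2, _ = synthesize_scan(f, lh200, geometry, cfg)
        assert np.array_equal(s1.amplitudes, s2.amplitudes)

    def test_noise_sd_matches_configured_accuracy(self, lh200, geometry):
        """Over >=1e4 measurements the reflection-coefficient error sd
        lands within 10% of the configured 0.0015."""
        f = uniform_field(0.45)
        cfg = ScanConfig(n_waveforms=12000, noise_sigma=0.0015, seed=3)
        scan, ref = synthesize_scan(f, lh200, geometry, cfg)
        series = compute_reflection_series(scan, ref)
        on_datum = geometry.in_datum(cfg.measurement_angles())
        r_true = fresnel_reflection(
            index_from_density(0.45, lh200.solid_refractive_index),
            geometry.container_index)
        err = series.r[~on_datum] - r_true
        assert err.size >= 10_000
        assert abs(err.std() - 0.0015) / 0.0015 < 0.10


class TestFillWeights:
    def test_uniform_field_equal_weights(self, lh200):
        f = uniform_field(0.45)
        tbl = synthesize_fill_weights(f, DosingEvent(), lh200, efficiency=1.0,
                                      weight_noise_sd_mg=0.0)
        assert tbl.shape == (8, 3)
        assert tbl["weight_mg"].nunique() == 1
        assert list(tbl["position"]) == [f"M{k:02d}" for k in range(1, 9)]

    def test_weights_monotone_in_density(self, lh200):
        f1, f2 = uniform_field(0.40, stage=0), uniform_field(0.50, stage=1)
        tbl = synthesize_fill_weights([f1, f2], DosingEvent(), lh200,
                                      weight_noise_sd_mg=0.0)
        w1 = tbl.loc[tbl.stage == 0, "weight_mg"]
        w2 = tbl.loc[tbl.stage == 1, "weight_mg"]
        assert w2.min() > w1.max()

    def test_hand_computed_weight(self, lh200):
        """density x true density x chamber volume, in mg."""
        f = uniform_field(0.45)
        tbl = synthesize_fill_weights(
            f, DosingEvent(), lh200, dosator_diameter_mm=3.4,
            chamber_length_mm=5.0, efficiency=1.0, weight_noise_sd_mg=0.0)
        expected = 0.45 * 1.543 * (np.pi / 4 * 3.4**2 * 5.0)
        assert tbl["weight_mg"].iloc[0] == pytest.approx(expected)

    def test_negative_weights_rejected_or_resampled(self, lh200):
        f = uniform_field(0.001, n_cells=8)
        with pytest.raises(ValueError):
            synthesize_fill_weights(f, DosingEvent(), lh200,
                                    weight_noise_sd_mg=50.0, seed=0)
        tbl = synthesize_fill_weights(f, DosingEvent(), lh200,
                                      weight_noise_sd_mg=0.05, seed=0,
                                      on_negative="resample")
        assert (tbl["weight_mg"] > 0).all()
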