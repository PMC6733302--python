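"""Peak extraction, reference normalisation, filtering, rotation
registration and angular binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thzpowder import (
    ScanConfig,
    Waveform,
    bin_angular,
    compute_reflection_series,
    detect_rotations,
    extract_peak_amplitude,
    moving_average,
    synthesize_scan,
)
from thzpowder.signal import (
    DatumNotFoundError,
    IncompleteRotationError,
    ReflectionSeries,
    ScanSequence,
)
from thzpowder.simulate import ricker_pulse


def pulse_waveform(amplitudes_at, n=451, window=45.0):
    """Trace that is a sum of narrow pulses: {center_ps: amplitude}."""
    t = np.linspace(0.0, window, n)
    a = np.zeros(n)
    for center, amp in amplitudes_at.items():
        a += amp * ricker_pulse(t, center, 0.5)
    return Waveform(t, a)


class TestPeakExtraction:
    def test_single_positive_pulse(self):
        w = pulse_waveform({20.0: 0.7})
        assert extract_peak_amplitude(w, gate=(15.0, 25.0)) == pytest.approx(0.7)

    def test_gate_excludes_larger_out_of_gate_pulse(self):
        w = pulse_waveform({20.0: -0.5, 40.0: 0.9})
        assert extract_peak_amplitude(w, gate=(15.0, 25.0)) == pytest.approx(
            -0.5, abs=1e-6
        )

    def test_all_zero_trace_warns_and_returns_zero(self):
        w = Waveform(np.linspace(0, 45, 10), np.zeros(10))
        with pytest.warns(UserWarning, match="all-zero"):
            assert extract_peak_amplitude(w) == 0.0

    def test_empty_gate_rejected(self):
        w = pulse_waveform({20.0: 0.7})
        with pytest.raises(ValueError, match="gate"):
            extract_peak_amplitude(w, gate=(100.0, 110.0))


class TestReflectionSeries:
    def test_datum_magnitude_equals_reference(self):
        delay = np.linspace(0, 45, 301)
        pulse = ricker_pulse(delay, 22.5)
        ref = Waveform(delay, -pulse)
        scan = ScanSequence(delay, np.vstack([-pulse, 0.1 * pulse]),
                            acquisition_rate=15.0, rotation_speed=4.0)
        series = compute_reflection_series(scan, ref)
        assert series.r[0] == pytest.approx(-1.0)  # datum candidate
        assert abs(series.r[0]) == pytest.approx(1.0)

    def test_zero_peak_gives_zero_r(self):
        delay = np.linspace(0, 45, 301)
        pulse = ricker_pulse(delay, 22.5)
        ref = Waveform(delay, -pulse)
        scan = ScanSequence(delay, np.vstack([np.zeros_like(pulse), pulse]),
                            acquisition_rate=15.0, rotation_speed=4.0)
        assert compute_reflection_series(scan, ref).r[0] == 0.0

    def test_zero_reference_is_fatal(self):
        delay = np.linspace(0, 45, 10)
        ref = Waveform(delay, np.zeros(10))
        scan = ScanSequence(delay, np.ones((3, 10)), 15.0, 4.0)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="reference"):
                compute_reflection_series(scan, ref)

    def test_round_trip_recovers_known_r_field(self, lh200, geometry,
                                               locked_scan_config):
        from thzpowder import fresnel_reflection, index_from_density
        from thzpowder.simulate import make_density_field

        f = make_density_field(lh200, geometry, heterogeneity_amp=0.015,
                               seed=9, n_cells=225)[0]
        scan, ref = synthesize_scan(f, lh200, geometry, locked_scan_config)
        series = compute_reflection_series(scan, ref)
        theta = locked_scan_config.measurement_angles()
        keep = ~geometry.in_datum(theta)
        expected = fresnel_reflection(
            index_from_density(f.density_at(theta[keep]),
                               lh200.solid_refractive_index),
            geometry.container_index)
        assert np.max(np.abs(series.r[keep] - expected)) < 1e-12


class TestMovingAverage:
    def test_constant_sequence_unchanged(self):
        assert np.allclose(moving_average(np.full(20, 3.3), 5), 3.3)

    def test_center_of_ramp(self):
        out = moving_average(np.array([1.0, 2, 3, 4, 5]), 5)
        assert out[2] == pytest.approx(3.0)

    @given(st.integers(0, 2**31 - 1), st.sampled_from([1, 3, 5, 7]))
    @settings(max_examples=50, derandomize=True)
    def test_matches_brute_force_with_mask(self, seed, window):
        rng = np.random.default_rng(seed)
        n = 40
        x = rng.normal(size=n)
        mask = rng.random(n) < 0.2
        out = moving_average(x, window, mask=mask)
        half = window // 2
        for i in range(n):
            lo, hi = max(0, i - half), min(n, i + half + 1)
            vals = [x[j] for j in range(lo, hi) if not mask[j]]
            if vals:
                assert out[i] == pytest.approx(np.mean(vals), abs=1e-14)
            else:
                assert np.isnan(out[i])

    @pytest.mark.parametrize("window", [0, 2, 4])
    def test_even_or_zero_window_rejected(self, window):
        with pytest.raises(ValueError):
            moving_average(np.ones(10), window)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            moving_average(np.ones(3), 5)


def synthetic_series(lh200, geometry, config, rho=0.45, heterogeneity=0.0,
                     seed=0):
    from thzpowder.simulate import make_density_field
    from thzpowder.specs import DensityField

    if heterogeneity:
        f = make_density_field(lh200, geometry,
                               heterogeneity_amp=heterogeneity, seed=seed,
                               n_cells=225)[0]
    else:
        f = DensityField(np.arange(225) * 1.6, np.full(225, rho))
    scan, ref = synthesize_scan(f, lh200, geometry, config)
    return f, compute_reflection_series(scan, ref)


class TestRotationDetection:
    def test_nominal_acquisition_yields_eight_complete(self, lh200, geometry,
                                                       locked_scan_config):
        _, series = synthetic_series(lh200, geometry, locked_scan_config)
        rot = detect_rotations(series)
        assert rot.n_complete == 8
        assert rot.has_trailing_partial

    def test_single_passage_is_an_error(self, lh200, geometry):
        cfg = ScanConfig(n_waveforms=200, noise_sigma=0.0)  # < 1 rotation
        _, series = synthetic_series(lh200, geometry, cfg)
        with pytest.raises(IncompleteRotationError, match="complete rotation"):
            detect_rotations(series)

    def test_threshold_above_all_r_is_an_error(self, lh200, geometry,
                                               locked_scan_config):
        _, series = synthetic_series(lh200, geometry, locked_scan_config)
        with pytest.raises(DatumNotFoundError, match="no datum"):
            detect_rotations(series, datum_threshold=2.0)

    def test_rotation_ids_assigned(self, lh200, geometry, locked_scan_config):
        _, series = synthetic_series(lh200, geometry, locked_scan_config)
        rot = detect_rotations(series)
        assert series.rotation_id[rot.passage_starts[0]] == 0
        assert series.rotation_id[-1] == -1  # trailing partial


class TestAngularBinning:
    def test_constant_series_constant_profile(self, lh200, geometry,
                                              locked_scan_config):
        _, series = synthetic_series(lh200, geometry, locked_scan_config)
        rot = detect_rotations(series)
        prof = bin_angular(series, rot, n_bins=225)
        assert np.allclose(prof.value[prof.valid], series.r[10], atol=1e-14)

    def test_default_bin_count(self, lh200, geometry, locked_scan_config):
        _, series = synthetic_series(lh200, geometry, locked_scan_config)
        rot = detect_rotations(series)
        prof = bin_angular(series, rot)
        assert prof.n_bins == 230

    def test_sinusoid_recovered_at_bin_centers(self, lh200, geometry):
        """A smooth sinusoidal r(θ) binned over 7 noiseless rotations
        matches the ground truth to within the discretisation bound."""
        cfg = ScanConfig(noise_sigma=0.0, rotation_speed=3.83)
        n_cells = 720
        theta = np.arange(n_cells) * 360.0 / n_cells
        rho = 0.45 + 0.02 * np.sin(np.radians(theta))
        from thzpowder.specs import DensityField
        from thzpowder import fresnel_reflection, index_from_density

        f = DensityField(theta, rho)
        scan, ref = synthesize_scan(f, lh200, geometry, cfg)
        series = compute_reflection_series(scan, ref)
        rot = detect_rotations(series)
        prof = bin_angular(series, rot, n_bins=230,
                           use_rotations=range(min(7, rot.n_complete)))
        expected = fresnel_reflection(
            index_from_density(0.45 + 0.02 * np.sin(
                np.radians(prof.bin_centers[prof.valid])),
                lh200.solid_refractive_index),
            geometry.container_index)
        # bound: max |dr/dθ| x (bin width + field cell width)
        slope = np.max(np.abs(np.diff(
            fresnel_reflection(index_from_density(
                rho, lh200.solid_refractive_index),
                geometry.container_index)))) / (360.0 / n_cells)
        bound = slope * (360.0 / 230 + 360.0 / n_cells)
        assert np.max(np.abs(prof.value[prof.valid] - expected)) < bound

    def test_empty_bins_reported_not_interpolated(self, lh200, geometry,
                                                  locked_scan_config):
        _, series = synthetic_series(lh200, geometry, locked_scan_config)
        rot = detect_rotations(series)
        prof = bin_angular(series, rot, n_bins=450)  # 2x the samples/rotation
        assert (prof.n_contributing == 0).any()
        assert np.isnan(prof.value[prof.n_contributing == 0]).all()

    def test_averaging_conservation(self, lh200, geometry):
        """Count-weighted profile mean equals the mean of contributing
        raw values to 1e-12."""
        cfg = ScanConfig(noise_sigma=0.002, seed=21)
        _, series = synthetic_series(lh200, geometry, cfg, heterogeneity=0.01,
                                     seed=4)
        rot = detect_rotations(series)
        use = range(min(7, rot.n_complete))
        prof = bin_angular(series, rot, n_bins=225, use_rotations=use)
        contributing = np.concatenate([
            np.arange(*rot.intervals[k]) for k in use])
        keep = ~series.datum_mask[contributing]
        raw_mean = series.r[contributing[keep]].mean()
        assert prof.weighted_mean == pytest.approx(raw_mean, abs=1e-12)

    def test_registration_invariant_to_start_offset(self, lh200, geometry):
        """Dropping the first measurements only rotates (here: leaves
        unchanged) the datum-referenced profile."""
        cfg = ScanConfig(noise_sigma=0.0)
        f, series = synthetic_series(lh200, geometry, cfg, heterogeneity=0.015,
                                     seed=6)
        rot = detect_rotations(series)
        prof_a = bin_angular(series, rot, n_bins=225, use_rotations=range(5))

        shifted = ReflectionSeries(r=series.r[100:].copy())
        rot_b = detect_rotations(shifted)
        prof_b = bin_angular(shifted, rot_b, n_bins=225,
                             use_rotations=range(5))
        both = prof_a.valid & prof_b.valid
        a = prof_a.value[both] - prof_a.value[both].mean()
        b = prof_b.value[both] - prof_b.value[both].mean()
        corr = np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b))
        assert corr >= 0.999
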