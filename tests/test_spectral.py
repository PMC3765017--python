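"""Spectral pipeline: segmentation, windowed spectra, tremor metrics."""

from dataclasses import replace

import numpy as np
import pytest

import actometry as am
from actometry.spectral import (
    DegenerateSpectrumError,
    FzSeries,
    PowerSpectrum,
    _band_integral,
    _half_power_crossings,
)


def _tone_fz(freq, seconds=60.0, fs=100.0, amp=1.0, offset=100.0):
    t = np.arange(int(seconds * fs)) / fs
    return FzSeries(offset + amp * np.sin(2 * np.pi * freq * t), fs)


class TestNetForceAndNormalization:
    def test_net_force_sums_channels(self, meta):
        forces = np.tile([1.0, 2.0, 3.0, 4.0], (10, 1))
        rec = am.Recording(forces=forces, sample_rate=100.0, meta=meta)
        assert np.all(am.net_force(rec) == 10.0)

    def test_motionless_twitcher_sits_at_100_percent(self):
        # a 10.4 g animal standing still loads exactly its body weight
        meta = am.AnimalMeta("t", "Twi", body_weight_g=10.4)
        fz = am.normalize_to_body_weight(np.full(100, 10.4), meta)
        np.testing.assert_allclose(fz.values, 100.0)

    def test_linear_map(self):
        meta = am.AnimalMeta("t", "Wt", body_weight_g=20.0)
        fz = am.normalize_to_body_weight(np.array([5.0]), meta)
        assert fz.values[0] == pytest.approx(25.0)

    def test_joint_rescaling_cancels(self):
        rng = np.random.default_rng(0)
        raw = 10.0 + rng.normal(0, 1, 500)
        a = am.normalize_to_body_weight(raw, am.AnimalMeta("t", "Wt", 10.0))
        b = am.normalize_to_body_weight(raw * 3.0, am.AnimalMeta("t", "Wt", 30.0))
        np.testing.assert_allclose(a.values, b.values)


class TestSegmentation:
    def test_first_minute_gives_12_segments_of_500(self):
        fz = FzSeries(np.zeros(6000), 100.0)
        segs = am.segment_series(fz)
        assert segs.shape == (12, 500)

    def test_longer_recording_still_uses_first_minute(self):
        fz = FzSeries(np.zeros(36000), 100.0)
        assert am.segment_series(fz).shape == (12, 500)

    def test_five_second_series_gives_one_segment(self):
        assert am.segment_series(FzSeries(np.zeros(500), 100.0)).shape == (1, 500)

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError):
            am.segment_series(FzSeries(np.zeros(499), 100.0))

    def test_trailing_partial_segment_discarded(self):
        assert am.segment_series(FzSeries(np.zeros(1234), 100.0)).shape == (2, 500)


class TestSegmentSpectrum:
    def test_bin_grid_is_fifth_of_hz(self):
        spec = am.segment_spectrum(np.zeros(500) + 1.0)
        assert spec.frequencies.size == 251
        np.testing.assert_allclose(np.diff(spec.frequencies), 0.2)

    def test_exact_bin_tone_peaks_at_its_bin(self):
        t = np.arange(500) / 100.0
        spec = am.segment_spectrum(np.sin(2 * np.pi * 12.0 * t))
        peak = spec.frequencies[np.argmax(spec.power)]
        assert peak == pytest.approx(12.0)
        # Hanning leakage confined to the immediate neighbors
        far = np.abs(spec.frequencies - 12.0) > 0.41
        assert spec.power[far].max() < 1e-6 * spec.power.max()

    def test_constant_segment_gives_zero_spectrum(self):
        spec = am.segment_spectrum(np.full(500, 17.0))
        np.testing.assert_allclose(spec.power, 0.0, atol=1e-20)

    def test_single_segment_parseval_near_variance(self):
        # one 500-sample windowed segment estimates the variance with a
        # sampling sd of ~6% (effective-n of the Hanning weights), so a
        # single draw agrees loosely; the averaged estimator is tested
        # tightly below.
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500)
        spec = am.segment_spectrum(x)
        assert spec.power.sum() == pytest.approx(np.var(x), rel=0.25)

    def test_averaged_parseval_within_5_percent(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(6000)
        segs = x.reshape(12, 500)
        avg = am.average_spectra([am.segment_spectrum(s) for s in segs], band=(0.0, 50.0))
        var = np.mean([np.var(s) for s in segs])
        assert avg.total_power() == pytest.approx(var, rel=0.05)

    def test_nonfinite_samples_rejected(self):
        x = np.zeros(500)
        x[3] = np.nan
        with pytest.raises(ValueError):
            am.segment_spectrum(x)


class TestAveraging:
    def _flat(self, value):
        f = np.arange(0, 50.2, 0.2)
        return PowerSpectrum(f, np.full(f.size, float(value)), (0.0, 50.0))

    def test_mean_is_idempotent(self):
        s = self._flat(3.0)
        avg = am.average_spectra([s] * 12, band=(0.0, 50.0))
        np.testing.assert_allclose(avg.power, 3.0)

    def test_binwise_mean(self):
        avg = am.average_spectra([self._flat(0.0), self._flat(2.0)], band=(0.0, 50.0))
        np.testing.assert_allclose(avg.power, 1.0)

    def test_band_restriction_closed_interval(self):
        avg = am.average_spectra([self._flat(1.0)])
        assert avg.frequencies.min() == pytest.approx(2.6, abs=0.21)
        assert avg.frequencies[0] >= 2.5 - 1e-9
        assert avg.frequencies[-1] <= 30.0 + 1e-9
        # 2.6..30.0 inclusive on the 0.2 Hz grid
        assert avg.frequencies.size == 138

    def test_mismatched_grids_rejected(self):
        a = self._flat(1.0)
        b = PowerSpectrum(np.arange(0, 25.1, 0.1), np.ones(251), (0.0, 25.0))
        with pytest.raises(ValueError):
            am.average_spectra([a, b])


class TestSpectralMetrics:
    def _spectrum(self, f, p):
        return PowerSpectrum(np.asarray(f, float), np.asarray(p, float), (2.5, 30.0))

    def test_rectangular_band(self):
        f = np.arange(2.6, 30.01, 0.2)
        p = np.where((f >= 10.0 - 1e-9) & (f <= 14.0 + 1e-9), 1.0, 0.0)
        m = am.spectral_metrics(self._spectrum(f, p))
        assert m.freq_at_peak_hz == pytest.approx(10.0)  # tie -> lowest
        assert m.center_frequency_hz == pytest.approx(12.0, abs=0.1)
        assert m.bandwidth_hz == pytest.approx(4.0, abs=0.25)

    def test_single_bin_peak(self):
        f = np.arange(2.6, 30.01, 0.2)
        p = np.zeros(f.size)
        p[np.argmin(np.abs(f - 12.0))] = 5.0
        m = am.spectral_metrics(self._spectrum(f, p))
        assert m.center_frequency_hz == pytest.approx(12.0, abs=0.01)
        assert m.bandwidth_hz <= 0.4 + 1e-9

    def test_band_power_zero_when_all_power_below_13(self):
        f = np.arange(2.6, 30.01, 0.2)
        p = np.where(f < 10.0, 1.0, 0.0)
        m = am.spectral_metrics(self._spectrum(f, p))
        assert m.band_power_13_20 == pytest.approx(0.0, abs=1e-12)

    def test_center_is_midpoint_of_crossings(self):
        rng = np.random.default_rng(2)
        f = np.arange(2.6, 30.01, 0.2)
        p = rng.random(f.size) + 0.01
        lo, hi = _half_power_crossings(f, p)
        m = am.spectral_metrics(self._spectrum(f, p))
        assert lo <= m.center_frequency_hz <= hi
        assert m.center_frequency_hz == pytest.approx((lo + hi) / 2.0)
        assert m.bandwidth_hz == pytest.approx(hi - lo)

    def test_all_zero_spectrum_flagged(self):
        f = np.arange(2.6, 30.01, 0.2)
        with pytest.raises(DegenerateSpectrumError):
            am.spectral_metrics(self._spectrum(f, np.zeros(f.size)))

    def test_band_integral_interpolates_endpoints(self):
        f = np.arange(2.6, 30.01, 0.2)
        val = _band_integral(f, np.ones(f.size), (13.0, 20.0))
        assert val == pytest.approx(7.0)
        # endpoints between bins
        val2 = _band_integral(f, np.ones(f.size), (13.1, 19.9))
        assert val2 == pytest.approx(6.8)


class TestAnalyzeRecording:
    def test_exact_bin_tone_recovery(self, tone_recording):
        spec, m = am.analyze_recording(tone_recording)
        assert m.freq_at_peak_hz == pytest.approx(12.0)
        assert m.center_frequency_hz == pytest.approx(12.0, abs=0.2)

    def test_oscillation_scaling_is_quadratic_in_power(self, meta):
        t = np.arange(6000) / 100.0
        osc = np.sin(2 * np.pi * 15.8 * t)
        recs = []
        for c in (1.0, 3.0):
            fz = meta.body_weight_g * (1.0 + 0.01 * c * osc)
            recs.append(
                am.Recording(np.tile((fz / 4)[:, None], (1, 4)), 100.0, meta)
            )
        _, m1 = am.analyze_recording(recs[0])
        _, m3 = am.analyze_recording(recs[1])
        assert m3.peak_power == pytest.approx(9.0 * m1.peak_power, rel=1e-9)
        assert m3.band_power_13_20 == pytest.approx(9.0 * m1.band_power_13_20, rel=1e-9)

    def test_symmetric_broadband_centroid_near_center(self, stationary_tremor_config):
        rec = am.simulate_recording(stationary_tremor_config, seed=11, duration_s=60)
        _, m = am.analyze_recording(rec)
        assert m.center_frequency_hz == pytest.approx(15.8, abs=0.5)

    def test_motionless_recording_has_no_tremor_metrics(self, motionless_config):
        rec = am.simulate_recording(motionless_config, seed=0, duration_s=60)
        with pytest.raises(DegenerateSpectrumError):
            am.analyze_recording(rec)

    def test_too_short_recording_propagates(self, meta):
        rec = am.Recording(np.ones((499, 4)), 100.0, meta)
        with pytest.raises(ValueError):
            am.analyze_recording(rec)
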