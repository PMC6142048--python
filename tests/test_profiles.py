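"""Depth-profile operations: RMS localization, alignment, band power, Welch PSD."""

import numpy as np
import pytest

import lamprobe as lp
from lamprobe.profiles import BandSet, DepthProfile, multitaper_psd
from lamprobe.recording import InvalidParameterError

from conftest import make_recording


def profile_of(values):
    values = np.asarray(values, dtype=float)
    return DepthProfile(values=values, depths_um=200.0 * np.arange(values.size), band="test")


class TestMuaRmsProfile:
    def test_zero_recording_zero_profile(self):
        rec = make_recording(np.zeros((4, 20000)), 20000.0)
        prof = lp.mua_rms_profile(rec)
        assert np.all(prof.values == 0)

    def test_sinusoid_rms_analytic(self):
        fs = 20000.0
        t = np.arange(0, 2.0, 1 / fs)
        data = np.zeros((4, t.size))
        data[2] = 80.0 * np.sin(2 * np.pi * 1000 * t)
        prof = lp.mua_rms_profile(make_recording(data, fs))
        assert prof.values[2] == pytest.approx(80.0 / np.sqrt(2), rel=0.05)
        assert np.argmax(prof.values) == 2

    def test_ground_truth_spike_channel_recovered(self, mua_recording):
        config, rec, _ = mua_recording
        prof = lp.mua_rms_profile(rec)
        lo, hi = config.layer_map.ranges["pyramidale"]
        assert lo <= lp.find_pyramidal_channel(prof) < hi


class TestFindPyramidalChannel:
    def test_simple_max(self):
        assert lp.find_pyramidal_channel(profile_of([1, 5, 2])) == 1

    def test_tie_breaks_dorsal(self):
        assert lp.find_pyramidal_channel(profile_of([5, 5, 1])) == 0

    def test_all_zero_warns_and_returns_zero(self, caplog):
        with caplog.at_level("WARNING"):
            assert lp.find_pyramidal_channel(profile_of([0, 0, 0])) == 0
        assert any("no power" in r.message for r in caplog.records)


class TestAlignAtPeak:
    def _gaussian_profiles(self, peaks, n=31):
        x = np.arange(n)
        return [profile_of(np.exp(-0.5 * ((x - p) / 2.0) ** 2)) for p in peaks]

    def test_peak_spread_six_retains_25_of_31(self):
        aligned = lp.align_at_peak(self._gaussian_profiles([4, 6, 8, 10]))
        assert aligned.n_retained == 25

    def test_identical_peaks_retain_all(self):
        aligned = lp.align_at_peak(self._gaussian_profiles([5, 5, 5]))
        assert aligned.n_retained == 31

    def test_extreme_spread_retains_one(self):
        aligned = lp.align_at_peak(self._gaussian_profiles([0, 30]))
        assert aligned.n_retained == 1

    def test_alignment_idempotent(self):
        aligned = lp.align_at_peak(self._gaussian_profiles([4, 6, 8]))
        again = lp.align_at_peak([profile_of(row) for row in aligned.aligned])
        assert again.n_retained == aligned.n_retained
        assert np.allclose(again.aligned, aligned.aligned)

    def test_peaks_coincide_after_alignment(self):
        aligned = lp.align_at_peak(self._gaussian_profiles([4, 9, 6]))
        peak_cols = np.argmax(aligned.aligned, axis=1)
        assert np.all(peak_cols == peak_cols[0])

    def test_non_finite_profile_rejected(self):
        bad = profile_of(np.full(31, np.nan))
        with pytest.raises(InvalidParameterError):
            lp.align_at_peak([bad, profile_of(np.ones(31))])


class TestDownsample:
    def test_amplitude_preserved(self):
        fs = 32000.0
        t = np.arange(0, 5.0, 1 / fs)
        rec = make_recording(100 * np.sin(2 * np.pi * 100 * t), fs)
        out = lp.downsample(rec, 2000.0)
        amp = np.abs(out.data[0, 1000:-1000]).max()
        assert abs(amp - 100.0) / 100.0 < 0.02

    def test_content_above_new_nyquist_removed(self):
        fs = 32000.0
        t = np.arange(0, 5.0, 1 / fs)
        rec = make_recording(100 * np.sin(2 * np.pi * 1500 * t), fs)
        out = lp.downsample(rec, 2000.0)
        assert np.abs(out.data[0, 1000:-1000]).max() < 10.0

    def test_output_length(self):
        rec = make_recording(np.zeros(32000 * 10), 32000.0)
        out = lp.downsample(rec, 3000.0)
        assert out.n_samples == 30000

    def test_upsampling_rejected(self):
        rec = make_recording(np.zeros(1000), 2000.0)
        with pytest.raises(InvalidParameterError):
            lp.downsample(rec, 3000.0)


class TestBandPowerProfile:
    def test_zero_signal_zero_power(self):
        rec = make_recording(np.zeros((3, 4000)), 2000.0)
        profiles = lp.band_power_profile(rec)
        for prof in profiles.values():
            assert np.all(prof.values == 0)

    def test_theta_tone_lands_in_theta_band(self):
        fs = 2000.0
        t = np.arange(0, 10.0, 1 / fs)
        data = np.zeros((9, t.size))
        data[7] = 50.0 * np.sin(2 * np.pi * 6 * t)
        profiles = lp.band_power_profile(make_recording(data, fs))
        theta = profiles["theta"].values[7]
        for name in ("low_gamma", "high_gamma", "ripple"):
            assert theta >= 10.0 * max(profiles[name].values[7], 1e-12)
        assert np.argmax(profiles["theta"].values) == 7

    def test_white_noise_profile_flat_across_channels(self):
        rng = np.random.default_rng(3)
        rec = make_recording(rng.normal(0, 10, (5, 120000)), 2000.0)
        profiles = lp.band_power_profile(rec)
        for prof in profiles.values():
            m = prof.values.mean()
            assert np.all(np.abs(prof.values - m) < 0.2 * m)

    def test_band_above_nyquist_rejected(self):
        rec = make_recording(np.zeros((3, 2000)), 400.0)
        with pytest.raises(InvalidParameterError):
            lp.band_power_profile(rec, BandSet())

    def test_parseval_on_white_noise(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 10, 2000)
        freqs, psd = multitaper_psd(x, 2000.0)
        total = np.trapezoid(psd, freqs)
        assert abs(total - x.var()) / x.var() < 0.05

    def test_generator_theta_envelope_peaks_in_radiatum(self, lfp_recording):
        config, rec, _ = lfp_recording
        profiles = lp.band_power_profile(rec)
        lo, hi = config.layer_map.ranges["radiatum"]
        assert lo <= np.argmax(profiles["theta"].values) < hi


class TestWelchPsd:
    FS = 2000.0

    def test_five_hz_tone_peak(self):
        t = np.arange(0, 20.0, 1 / self.FS)
        freqs, psd = lp.welch_psd_1_20(100 * np.sin(2 * np.pi * 5 * t), self.FS)
        assert abs(freqs[np.argmax(psd)] - 5.0) <= 0.2
        assert psd.max() == 1.0

    def test_frequency_grid_spacing(self):
        t = np.arange(0, 5.0, 1 / self.FS)
        freqs, _ = lp.welch_psd_1_20(np.sin(2 * np.pi * 3 * t), self.FS)
        assert np.allclose(np.diff(freqs), 0.2)
        assert freqs.min() >= 1.0 and freqs.max() <= 20.0

    def test_two_tone_power_ratio(self):
        t = np.arange(0, 30.0, 1 / self.FS)
        x = 2.0 * np.sin(2 * np.pi * 3 * t) + 1.0 * np.sin(2 * np.pi * 8 * t)
        freqs, psd = lp.welch_psd_1_20(x, self.FS)
        ratio = psd[np.argmin(np.abs(freqs - 8))] / psd[np.argmin(np.abs(freqs - 3))]
        assert ratio == pytest.approx(0.25, rel=0.2)

    def test_short_signal_rejected(self):
        with pytest.raises(InvalidParameterError):
            lp.welch_psd_1_20(np.zeros(500), self.FS)


def test_pyramidal_layer_recovery_rate(mua_recording):
    """Across seeded recordings the MUA peak falls in the pyramidale range."""
    hits = 0
    n_runs = 20
    for seed in range(n_runs):
        config = lp.GeneratorConfig(duration=2.0, fs=20000.0, seed=seed)
        rec, _ = lp.simulate_recording(config)
        ch = lp.find_pyramidal_channel(lp.mua_rms_profile(rec))
        lo, hi = config.layer_map.ranges["pyramidale"]
        hits += int(lo <= ch < hi)
    assert hits >= 0.95 * n_runs
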