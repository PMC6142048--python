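"""Spike-band filtering, detection performance, and unit metric contracts."""

import numpy as np
import pytest

import lamprobe as lp
from lamprobe.recording import InvalidParameterError
from lamprobe.spiking import (
    FilteredSignal,
    NyquistError,
    autocorrelogram,
    bandpass_600_6000,
    detect_spikes,
    isi_histogram,
    rate_by_depth,
    unit_metrics,
    wavelet_highpass,
)
from lamprobe.synth import spike_template

from conftest import make_recording


class TestBandpass:
    FS = 32000.0

    def _tone(self, freq, amp=100.0, duration=1.0):
        t = np.arange(0, duration, 1 / self.FS)
        return make_recording(amp * np.sin(2 * np.pi * freq * t), self.FS)

    def test_dc_removed(self):
        rec = make_recording(np.full(32000, 100.0), self.FS)
        out = bandpass_600_6000(rec)
        assert np.abs(out.data).max() < 1.0

    def test_passband_unity_at_1khz(self):
        out = bandpass_600_6000(self._tone(1000.0))
        amp = np.abs(out.data[0, 8000:-8000]).max()
        assert abs(amp - 100.0) < 5.0

    def test_stopband_at_100hz(self):
        out = bandpass_600_6000(self._tone(100.0))
        assert np.abs(out.data[0, 8000:-8000]).max() < 10.0

    def test_nyquist_guard(self):
        rec = make_recording(np.zeros(1000), 10000.0)
        with pytest.raises(NyquistError):
            bandpass_600_6000(rec)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a = make_recording(rng.normal(0, 10, 16000), self.FS)
        b = make_recording(rng.normal(0, 10, 16000), self.FS)
        both = make_recording(2.0 * a.data[0] + b.data[0], self.FS)
        lhs = bandpass_600_6000(both).data
        rhs = 2.0 * bandpass_600_6000(a).data + bandpass_600_6000(b).data
        assert np.allclose(lhs, rhs, rtol=1e-6, atol=1e-9)


class TestWaveletHighpass:
    FS = 32000.0

    def test_constant_removed(self):
        rec = make_recording(np.full(32000, 50.0), self.FS)
        out = wavelet_highpass(rec)
        assert np.abs(out.data).max() < 0.5

    def test_50hz_power_mostly_removed(self):
        t = np.arange(0, 1.0, 1 / self.FS)
        rec = make_recording(100 * np.sin(2 * np.pi * 50 * t), self.FS)
        out = wavelet_highpass(rec)
        assert (out.data**2).mean() < 0.05 * (rec.data**2).mean()

    def test_spike_shape_agrees_with_bandpass(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 2, 32000)
        tmpl = spike_template(self.FS, 100.0)
        center = 16000
        x[center:center + tmpl.size] += tmpl
        rec = make_recording(x, self.FS)
        win = slice(center - 32, center + tmpl.size + 32)
        a = wavelet_highpass(rec).data[0, win]
        b = bandpass_600_6000(rec).data[0, win]
        r = np.corrcoef(a, b)[0, 1]
        # passbands differ (>=250 Hz vs 600-6000 Hz), which bounds the
        # achievable agreement; 0.9 reflects shape preservation
        assert r > 0.9

    def test_short_signal_rejected(self):
        rec = make_recording(np.zeros(32), 32000.0)
        with pytest.raises(InvalidParameterError):
            wavelet_highpass(rec)


class TestDetectSpikes:
    def test_false_positive_rate_on_pure_noise(self):
        config = lp.GeneratorConfig(
            duration=10.0, fs=20000.0, seed=6, units=(), band_envelopes={},
            spw_amplitude_uv=0.0,
        )
        rec, _ = lp.simulate_recording(config)
        events = detect_spikes(bandpass_600_6000(rec), k=5.0)
        per_channel_rate = np.array([e.size for e in events]) / rec.duration
        assert per_channel_rate.max() < 0.2

    def test_recall_and_precision_on_ground_truth(self, mua_recording):
        config, rec, truth = mua_recording
        events = detect_spikes(bandpass_600_6000(rec), k=5.0)
        channels = sorted(set(truth.spike_channels.values()))
        for ch in channels:
            gt = np.sort(np.concatenate([
                t for u, t in truth.spike_times.items()
                if truth.spike_channels[u] == ch
            ]))
            det = events[ch]
            d = np.abs(det[:, None] - gt[None, :])
            recall = (d.min(axis=0) < 5e-4).mean()
            precision = (d.min(axis=1) < 5e-4).mean()
            assert recall >= 0.95 and precision >= 0.95

    def test_recall_monotone_in_threshold(self, mua_recording):
        _, rec, truth = mua_recording
        filt = bandpass_600_6000(rec)
        ch = next(iter(truth.spike_channels.values()))
        gt = np.sort(np.concatenate([
            t for u, t in truth.spike_times.items() if truth.spike_channels[u] == ch
        ]))
        recalls = []
        for k in (4.0, 5.0, 6.0, 8.0):
            det = detect_spikes(filt, k=k)[ch]
            d = np.abs(det[:, None] - gt[None, :]) if det.size else np.empty((0, gt.size))
            recalls.append((d.min(axis=0) < 5e-4).mean() if det.size else 0.0)
        assert all(a >= b for a, b in zip(recalls, recalls[1:]))

    def test_empty_signal_gives_no_events(self):
        filt = FilteredSignal(data=np.empty((3, 0)), fs=20000.0, band="600-6000")
        assert all(e.size == 0 for e in detect_spikes(filt))


class TestUnitMetrics:
    def test_firing_rate_arithmetic(self):
        times = np.linspace(0.5, 179.5, 540)
        filt = FilteredSignal(data=np.zeros((1, 180000)), fs=1000.0, band="test")
        cluster, _, _ = unit_metrics(times, filt, channel=0)
        assert cluster.firing_rate_hz == pytest.approx(3.0)

    def test_periodic_train_isi_mass_in_100ms_bin(self):
        times = np.arange(0.1, 10.0, 0.1)
        hist = isi_histogram(times, max_ms=150.0, bin_ms=1.0)
        near_100 = (hist.bin_edges_ms[:-1] >= 99.0) & (hist.bin_edges_ms[:-1] <= 100.0)
        assert hist.counts[near_100].sum() == hist.counts.sum() == times.size - 1

    def test_poisson_autocorrelogram_flat(self):
        rng = np.random.default_rng(0)
        times = np.cumsum(rng.exponential(0.2, size=400))
        times = times[times < 60.0]
        acg = autocorrelogram(times, span_ms=50.0, bin_ms=1.0)
        centers = (acg.bin_edges_ms[:-1] + acg.bin_edges_ms[1:]) / 2
        outside = acg.counts[np.abs(centers) > 2.0]
        m = outside.mean()
        assert np.all(np.abs(outside - m) <= 5 * np.sqrt(m) + 3)

    def test_autocorrelogram_symmetric_zero_lag_excluded(self):
        times = np.array([0.0, 0.01, 0.03])
        acg = autocorrelogram(times, span_ms=50.0, bin_ms=1.0)
        assert np.array_equal(acg.counts, acg.counts[::-1])
        assert acg.counts.sum() == 6  # ordered pairs, no self-pairs

    def test_edge_events_dropped_and_counted(self):
        filt = FilteredSignal(data=np.zeros((1, 1000)), fs=1000.0, band="test")
        times = np.array([0.0005, 0.5, 0.9999])
        cluster, _, _ = unit_metrics(times, filt, channel=0, window_ms=4.0)
        assert cluster.n_dropped_edge == 2
        assert cluster.waveforms.shape[0] == 1

    def test_mean_waveform_converges_to_template(self):
        fs = 20000.0
        rng = np.random.default_rng(2)
        tmpl = spike_template(fs, 100.0)
        n_spikes, sigma = 100, 10.0
        x = rng.normal(0, sigma, int(fs * 30))
        step = int(0.25 * fs)
        idx = np.arange(n_spikes) * step + 1000
        for i in idx:
            x[i:i + tmpl.size] += tmpl
        filt = FilteredSignal(data=x[None, :], fs=fs, band="test")
        trough = idx + np.argmin(tmpl)
        cluster, _, _ = unit_metrics(trough / fs, filt, channel=0, window_ms=0.6)
        half = cluster.mean_waveform.size // 2
        ref = tmpl[np.argmin(tmpl) - half:np.argmin(tmpl) + half + 1]
        residual = cluster.mean_waveform - ref
        assert residual.std() < 3 * sigma / np.sqrt(n_spikes)

    def test_no_spikes_rejected(self):
        filt = FilteredSignal(data=np.zeros((1, 100)), fs=1000.0, band="test")
        with pytest.raises(InvalidParameterError):
            unit_metrics(np.array([]), filt, channel=0)


class TestRateByDepth:
    def test_single_depth_single_bin(self):
        table = rate_by_depth([2.0, 4.0], [500.0, 500.0])
        assert len(table) == 1
        assert table["mean_rate_hz"].iloc[0] == pytest.approx(3.0)

    def test_pig_span_gives_eight_bins(self):
        depths = np.linspace(0.0, 1598.9, 10)
        table = rate_by_depth(np.ones(10), depths, bin_width_um=200.0)
        assert len(table) == 8

    def test_empty_units_empty_table(self):
        assert len(rate_by_depth([], [])) == 0
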