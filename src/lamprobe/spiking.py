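"""Multiunit-band filtering, threshold spike detection, and unit metrics.

The multiunit band is 600-6000 Hz.  Two high-pass routes are provided: a
zero-phase Butterworth band-pass used for detection and RMS power, and a
wavelet multilevel decomposition/reconstruction filter (level 6, Daubechies 4)
that removes the slow LFP while distorting spike waveform shape less, used for
waveform display and averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal

from ._dsp import bandpass, mad_sigma
from .recording import InvalidParameterError, LaminarRecording

logger = logging.getLogger(__name__)

MUA_BAND = (600.0, 6000.0)


class NyquistError(InvalidParameterError):
    """Sampling rate too low for the requested band."""


@dataclass
class FilteredSignal:
    """Channels x time filtered trace with its band descriptor."""

    data: np.ndarray
    fs: float
    band: str

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class UnitCluster:
    """Spike times and waveform statistics for one putative unit."""

    unit_id: int
    channel: int
    times: np.ndarray  # s, strictly increasing
    waveforms: np.ndarray  # events x samples, µV
    mean_waveform: np.ndarray
    sd_waveform: np.ndarray
    firing_rate_hz: float
    n_dropped_edge: int = 0


@dataclass
class IntervalHistogram:
    """ISI histogram or spike autocorrelogram."""

    bin_edges_ms: np.ndarray
    counts: np.ndarray
    kind: str  # "isi" or "autocorrelogram"


def bandpass_600_6000(recording: LaminarRecording, order: int = 3) -> FilteredSignal:
    """Zero-phase 600-6000 Hz Butterworth band-pass of every channel."""
    if recording.fs <= 12000:
        raise NyquistError(
            f"sampling rate {recording.fs} Hz cannot represent a 6 kHz band edge"
        )
    out = bandpass(recording.data, *MUA_BAND, recording.fs, order=order)
    return FilteredSignal(data=out, fs=recording.fs, band="600-6000 Hz bandpass")


def wavelet_highpass(
    recording: LaminarRecording, wavelet: str = "db4", level: int = 6
) -> FilteredSignal:
    """High-pass by wavelet multilevel decomposition and reconstruction.

    Decomposes each channel to ``level`` scales, zeroes the final
    approximation coefficients, and reconstructs: content below roughly
    fs / 2**(level+1) is removed with minimal waveform-shape distortion.
    """
    n = recording.n_samples
    if n < 2**level:
        raise InvalidParameterError(
            f"signal length {n} too short for a level-{level} decomposition"
        )
    out = np.empty_like(recording.data)
    for ch in range(recording.n_channels):
        coeffs = pywt.wavedec(recording.data[ch], wavelet, level=level)
        coeffs[0] = np.zeros_like(coeffs[0])
        rec = pywt.waverec(coeffs, wavelet)
        out[ch] = rec[:n]
    return FilteredSignal(
        data=out, fs=recording.fs, band=f"{wavelet} level-{level} highpass"
    )


def detect_spikes(
    filtered: FilteredSignal, k: float = 5.0, merge_ms: float = 1.0
) -> list[np.ndarray]:
    """Negative-threshold spike detection on each channel.

    The per-channel threshold is ``-k * sigma`` with the robust noise estimate
    ``sigma = median(|x|) / 0.6745``.  Events closer than ``merge_ms`` are
    merged keeping the deeper trough; the trough time is reported.

    Returns a list (one entry per channel) of event-time arrays in seconds.
    """
    if k <= 0:
        raise InvalidParameterError("threshold multiplier k must be positive")
    events: list[np.ndarray] = []
    distance = max(1, round(merge_ms / 1000.0 * filtered.fs))
    for ch in range(filtered.n_channels):
        x = filtered.data[ch]
        if x.size == 0:
            events.append(np.array([]))
            continue
        sigma = mad_sigma(x)
        if sigma == 0:
            events.append(np.array([]))
            continue
        peaks, _ = signal.find_peaks(-x, height=k * sigma, distance=distance)
        events.append(peaks / filtered.fs)
    return events


def unit_metrics(
    times: np.ndarray,
    filtered: FilteredSignal,
    channel: int,
    window_ms: float = 2.0,
    unit_id: int = 0,
    acg_span_ms: float = 50.0,
    acg_bin_ms: float = 1.0,
    isi_max_ms: float = 100.0,
    isi_bin_ms: float = 1.0,
) -> tuple[UnitCluster, IntervalHistogram, IntervalHistogram]:
    """Waveform statistics, firing rate, ISI histogram and autocorrelogram.

    Waveform snippets span ``window_ms`` centred on each trough; events whose
    window extends past the recording edge are dropped (counted and logged).
    Firing rate is spike count over recording duration.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise InvalidParameterError("unit_metrics requires at least one spike")
    half = round(window_ms / 2000.0 * filtered.fs)
    x = filtered.data[channel]
    idx = np.round(times * filtered.fs).astype(int)
    keep = (idx - half >= 0) & (idx + half < x.size)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("unit %d: dropped %d edge events", unit_id, n_dropped)
    snippets = np.stack([x[i - half:i + half + 1] for i in idx[keep]]) \
        if keep.any() else np.empty((0, 2 * half + 1))
    duration = filtered.duration
    cluster = UnitCluster(
        unit_id=unit_id,
        channel=channel,
        times=np.sort(times),
        waveforms=snippets,
        mean_waveform=snippets.mean(axis=0) if len(snippets) else snippets.sum(axis=0),
        sd_waveform=snippets.std(axis=0, ddof=1) if len(snippets) > 1
        else np.zeros(snippets.shape[1]),
        firing_rate_hz=times.size / duration,
        n_dropped_edge=n_dropped,
    )
    isi = isi_histogram(cluster.times, isi_max_ms, isi_bin_ms)
    acg = autocorrelogram(cluster.times, acg_span_ms, acg_bin_ms)
    return cluster, isi, acg


def isi_histogram(times: np.ndarray, max_ms: float = 100.0, bin_ms: float = 1.0) -> IntervalHistogram:
    edges = np.arange(0.0, max_ms + bin_ms, bin_ms)
    isis_ms = np.diff(np.sort(times)) * 1000.0
    counts, _ = np.histogram(isis_ms, bins=edges)
    return IntervalHistogram(bin_edges_ms=edges, counts=counts, kind="isi")


def autocorrelogram(times: np.ndarray, span_ms: float = 50.0, bin_ms: float = 1.0) -> IntervalHistogram:
    """Spike-train autocorrelogram over ±span, zero-lag self-pairs excluded.

    Bins are centred on integer multiples of ``bin_ms`` so the histogram is
    exactly symmetric about zero lag.
    """
    t = np.sort(times) * 1000.0
    edges = np.arange(-span_ms - bin_ms / 2, span_ms + bin_ms, bin_ms)
    lags = []
    # all ordered pairs within span (window advances: O(n * pairs-in-span))
    j0 = 0
    for i in range(t.size):
        while j0 < t.size and t[j0] < t[i] - span_ms:
            j0 += 1
        for j in range(j0, t.size):
            if t[j] > t[i] + span_ms:
                break
            if i != j:
                lags.append(t[j] - t[i])
    counts, _ = np.histogram(lags, bins=edges)
    return IntervalHistogram(bin_edges_ms=edges, counts=counts, kind="autocorrelogram")


def rate_by_depth(
    rates_hz: np.ndarray, depths_um: np.ndarray, bin_width_um: float = 200.0
):
    """Bin unit firing rates into contiguous ~bin_width depth bins.

    Returns a DataFrame with one row per bin: depth interval, mean rate, SEM
    (NaN for single-unit bins) and unit count.  The number of bins is
    ceil(depth span / bin width), minimum 1.
    """
    import math

    import pandas as pd

    rates_hz = np.asarray(rates_hz, dtype=float)
    depths_um = np.asarray(depths_um, dtype=float)
    if rates_hz.size == 0:
        return pd.DataFrame(
            columns=["depth_lo_um", "depth_hi_um", "mean_rate_hz", "sem_rate_hz", "n_units"]
        )
    if rates_hz.size != depths_um.size:
        raise InvalidParameterError("every unit needs a depth")
    lo = depths_um.min()
    span = depths_um.max() - lo
    n_bins = max(1, math.ceil(span / bin_width_um))
    which = np.minimum(((depths_um - lo) // bin_width_um).astype(int), n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = rates_hz[which == b]
        rows.append({
            "depth_lo_um": lo + b * bin_width_um,
            "depth_hi_um": lo + (b + 1) * bin_width_um,
            "mean_rate_hz": sel.mean() if sel.size else 0.0,
            "sem_rate_hz": sel.std(ddof=1) / np.sqrt(sel.size) if sel.size > 1 else np.nan,
            "n_units": sel.size,
        })
    return pd.DataFrame(rows)
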