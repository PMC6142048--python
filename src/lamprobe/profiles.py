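"""Depth profiling: layer localization from multiunit RMS power,
cross-subject peak alignment, and spectral band power as a function of depth.

The pyramidal cell layer is located as the channel with maximal RMS power in
the 600-6000 Hz multiunit band; profiles from several subjects are aligned at
that peak (channels not covered by every subject are cut off) before
averaging.  Band power by depth is computed on down-sampled LFPs with a
multitaper estimate on non-overlapping 1-s segments, integrated over each
band and averaged across segments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal
from scipy.signal.windows import dpss

from .recording import InvalidParameterError, LaminarRecording
from .spiking import bandpass_600_6000

logger = logging.getLogger(__name__)


@dataclass
class DepthProfile:
    """One non-negative scalar per channel, with depths, for one band."""

    values: np.ndarray
    depths_um: np.ndarray
    band: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.depths_um = np.asarray(self.depths_um, dtype=float)
        if self.values.shape != self.depths_um.shape:
            raise InvalidParameterError("profile values and depths differ in length")


@dataclass(frozen=True)
class BandSet:
    """Canonical hippocampal analysis bands (Hz)."""

    theta: tuple[float, float] = (4.0, 10.0)
    low_gamma: tuple[float, float] = (25.0, 55.0)
    high_gamma: tuple[float, float] = (55.0, 90.0)
    ripple: tuple[float, float] = (150.0, 250.0)

    def items(self):
        return [
            ("theta", self.theta),
            ("low_gamma", self.low_gamma),
            ("high_gamma", self.high_gamma),
            ("ripple", self.ripple),
        ]


@dataclass
class AlignedProfiles:
    """Per-subject profiles shifted so their peak channels coincide."""

    aligned: np.ndarray  # subjects x retained channels
    offsets: np.ndarray  # channel offset relative to the common peak
    peak_indices: np.ndarray
    mean: np.ndarray
    sem: np.ndarray

    @property
    def n_retained(self) -> int:
        return self.aligned.shape[1]


def mua_rms_profile(recording: LaminarRecording) -> DepthProfile:
    """Per-channel RMS of the 600-6000 Hz band over the whole recording."""
    filt = bandpass_600_6000(recording)
    rms = np.sqrt(np.mean(filt.data**2, axis=1))
    return DepthProfile(
        values=rms, depths_um=recording.channel_depths_um(), band="600-6000 Hz RMS"
    )


def find_pyramidal_channel(profile: DepthProfile) -> int:
    """Channel index of maximal profile power; ties go to the most dorsal."""
    if profile.values.size == 0:
        raise InvalidParameterError("empty profile")
    if not np.any(profile.values):
        logger.warning("profile has no power anywhere; returning channel 0")
        return 0
    return int(np.argmax(profile.values))


def align_at_peak(profiles: list[DepthProfile]) -> AlignedProfiles:
    """Shift profiles so their peaks coincide; drop non-overlapping channels.

    With peaks at indices p_j on n channels, the channels retained are those
    covered by every subject after shifting: n - (max(p) - min(p)) of them.
    """
    if len(profiles) < 2:
        raise InvalidParameterError("alignment needs at least two profiles")
    n = profiles[0].values.size
    if any(p.values.size != n for p in profiles):
        raise InvalidParameterError("profiles differ in channel count")
    for p in profiles:
        if not np.isfinite(p.values).any():
            raise InvalidParameterError("profile has no finite values")
    peaks = np.array([find_pyramidal_channel(p) for p in profiles])
    offsets = np.arange(-peaks.min(), n - peaks.max())
    aligned = np.stack([p.values[peaks[j] + offsets] for j, p in enumerate(profiles)])
    mean = aligned.mean(axis=0)
    sem = aligned.std(axis=0, ddof=1) / math.sqrt(len(profiles))
    return AlignedProfiles(
        aligned=aligned, offsets=offsets, peak_indices=peaks, mean=mean, sem=sem
    )


def downsample(recording: LaminarRecording, target_fs: float) -> LaminarRecording:
    """Anti-aliased polyphase resampling to the LFP analysis rate."""
    if target_fs >= recording.fs:
        raise InvalidParameterError("target rate must be below the source rate")
    frac = Fraction(target_fs / recording.fs).limit_denominator(10000)
    out = signal.resample_poly(recording.data, frac.numerator, frac.denominator, axis=1)
    n_expected = round(recording.duration * target_fs)
    out = out[:, :n_expected]
    return LaminarRecording(data=out, fs=target_fs, probe=recording.probe)


def multitaper_psd(
    x: np.ndarray, fs: float, nw: float = 3.0, n_tapers: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided multitaper PSD of a 1-D segment using DPSS tapers.

    Tapers are unit-energy Slepian sequences with time-bandwidth ``nw``;
    taper periodograms are averaged.  Satisfies Parseval: the integral of the
    PSD over 0..Nyquist estimates the segment variance.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    tapers = dpss(n, nw, Kmax=n_tapers)  # rows have unit energy
    spectra = np.abs(np.fft.rfft(tapers * x[None, :], axis=1)) ** 2 / fs
    psd = spectra.mean(axis=0)
    psd[1:] *= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    return freqs, psd


def band_power_profile(
    recording: LaminarRecording,
    bands: BandSet | None = None,
    segment_s: float = 1.0,
    nw: float = 3.0,
    n_tapers: int = 5,
) -> dict[str, DepthProfile]:
    """Integrated multitaper band power per channel, averaged over 1-s segments.

    The recording is cut into non-overlapping ``segment_s`` pieces (a trailing
    partial segment is discarded); each segment's multitaper spectrum is
    integrated (trapezoid) over every band and the segment values averaged.
    """
    bands = bands or BandSet()
    nyq = recording.fs / 2.0
    for name, (lo, hi) in bands.items():
        if hi >= nyq:
            raise InvalidParameterError(f"band {name} upper edge {hi} Hz >= Nyquist")
        if hi <= lo:
            raise InvalidParameterError(f"band {name} has non-positive width")
    nper = round(segment_s * recording.fs)
    n_seg = recording.n_samples // nper
    if n_seg < 1:
        raise InvalidParameterError("recording shorter than one segment")
    tapers = dpss(nper, nw, Kmax=n_tapers)
    freqs = np.fft.rfftfreq(nper, 1.0 / recording.fs)
    masks = {name: (freqs >= lo) & (freqs <= hi) for name, (lo, hi) in bands.items()}
    depths = recording.channel_depths_um()
    out = {name: np.zeros(recording.n_channels) for name, _ in bands.items()}
    for ch in range(recording.n_channels):
        segs = recording.data[ch, : n_seg * nper].reshape(n_seg, nper)
        # (segments, tapers, freqs) -> taper-averaged one-sided PSD
        spec = np.abs(np.fft.rfft(segs[:, None, :] * tapers[None, :, :], axis=2)) ** 2
        psd = spec.mean(axis=1) / recording.fs
        psd[:, 1:] *= 2.0
        if nper % 2 == 0:
            psd[:, -1] /= 2.0
        for name in out:
            band_power = np.trapezoid(psd[:, masks[name]], freqs[masks[name]], axis=1)
            out[name][ch] = band_power.mean()
    return {
        name: DepthProfile(values=vals, depths_um=depths, band=name)
        for name, vals in out.items()
    }


def welch_psd_1_20(
    x: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    overlap: float = 0.6,
    resolution_hz: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Peak-normalized Welch PSD on a 1-20 Hz grid with 0.2 Hz spacing.

    1-s Hann windows with 60% overlap; the 0.2 Hz grid is obtained by
    zero-padding each window five-fold (grid spacing, not true resolution).
    Returns ``(freqs, psd / psd.max())``.
    """
    x = np.asarray(x, dtype=float)
    nperseg = round(window_s * fs)
    if x.size < nperseg:
        raise InvalidParameterError("signal shorter than one Welch window")
    nfft = round(fs / resolution_hz)  # 5x zero-padding for 1-s windows
    freqs, psd = signal.welch(
        x, fs=fs, nperseg=nperseg, noverlap=round(overlap * nperseg), nfft=nfft
    )
    sel = (freqs >= 1.0) & (freqs <= 20.0)
    freqs, psd = freqs[sel], psd[sel]
    peak = psd.max()
    if peak > 0:
        psd = psd / peak
    return freqs, psd
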