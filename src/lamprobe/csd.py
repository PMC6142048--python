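"""Current source density, phase reversals, SPW-like events, evoked averaging.

CSD is the (negated) second spatial difference of the LFP across equally
spaced contacts: ``CSD_i = -(phi_{i-1} - 2 phi_i + phi_{i+1}) / pitch**2``,
so current sinks are negative.  Edge channels are dropped by default (no
assumption about the potential beyond the probe); Vaknin padding, which
replicates the edge channels to keep all contacts, is available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from ._dsp import bandpass
from .recording import InvalidParameterError, LaminarRecording

logger = logging.getLogger(__name__)


@dataclass
class CSDMap:
    """Interior-channel x time current source density; sinks are negative."""

    data: np.ndarray  # ∝ µV / µm²
    fs: float
    channel_indices: np.ndarray  # source-recording channel of each CSD row
    pitch_um: float


@dataclass
class EventList:
    """Detected transient events on one channel."""

    times: np.ndarray  # s, increasing
    peak_amplitudes: np.ndarray  # detection-trace value at the peak, µV
    channel: int
    band_hz: tuple[float, float]

    @property
    def n_events(self) -> int:
        return self.times.size


@dataclass
class EvokedResponse:
    """Per-channel trial-averaged post-stimulus response."""

    data: np.ndarray  # channels x window samples, µV
    fs: float
    window_s: float
    n_trials: int
    blank_ms: float
    n_dropped: int = 0


def csd_map(lfp: LaminarRecording, pitch_um: float | None = None,
            vaknin: bool = False) -> CSDMap:
    """Second-spatial-derivative CSD of a laminar LFP.

    With ``vaknin=True`` the edge channels are duplicated before
    differencing so every contact gets a CSD trace; otherwise the two edge
    channels are dropped (31 contacts -> 29 interior traces).
    """
    if lfp.n_channels < 3:
        raise InvalidParameterError("CSD needs at least 3 channels")
    pitch = pitch_um if pitch_um is not None else lfp.probe.pitch_um
    if pitch <= 0:
        raise InvalidParameterError("pitch must be positive")
    phi = lfp.data
    if vaknin:
        phi = np.vstack([phi[:1], phi, phi[-1:]])
        chans = np.arange(lfp.n_channels)
    else:
        chans = np.arange(1, lfp.n_channels - 1)
    csd = -(phi[:-2] - 2.0 * phi[1:-1] + phi[2:]) / pitch**2
    return CSDMap(data=csd, fs=lfp.fs, channel_indices=chans, pitch_um=pitch)


def detect_phase_reversals(
    lfp: LaminarRecording,
    band_hz: tuple[float, float] | None = (1.0, 5.0),
    threshold: float = -0.5,
) -> list[tuple[int, int]]:
    """Laminar boundaries where adjacent channels anticorrelate.

    Each channel is band-passed (skipped when ``band_hz`` is None, e.g. for
    short evoked averages) and the Pearson correlation of every adjacent
    channel pair computed; pairs below ``threshold`` are reported as
    ``(upper, lower)`` channel-index boundaries.
    """
    if lfp.n_channels < 2:
        raise InvalidParameterError("need at least 2 channels")
    if band_hz is not None:
        lo, hi = band_hz
        if lfp.duration < 10.0 / lo:
            raise InvalidParameterError(
                f"recording shorter than 10 cycles of the {lo} Hz band edge"
            )
        x = bandpass(lfp.data, lo, hi, lfp.fs)
    else:
        x = lfp.data
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1)
    boundaries = []
    for ch in range(lfp.n_channels - 1):
        denom = norms[ch] * norms[ch + 1]
        if denom == 0:
            continue
        r = float(np.dot(x[ch], x[ch + 1]) / denom)
        if r < threshold:
            boundaries.append((ch, ch + 1))
    return boundaries


def detect_spw_like(
    lfp: LaminarRecording,
    channel: int,
    band_hz: tuple[float, float] = (1.0, 20.0),
    k: float = 4.0,
    min_separation_s: float = 0.1,
    n_iter: int = 3,
) -> EventList:
    """Detect SPW-like waves on one (typically radiatum) channel.

    The channel is band-passed over a band wide enough that each wave appears
    as a discrete transient (default 1-20 Hz: a sharp wave lasting tens of
    milliseconds has spectral content well above its 2-3 Hz occurrence rate)
    and the magnitude of the analytic (Hilbert) signal, computed on a
    reflect-padded copy to suppress end transients, is the detection
    envelope.  The background scale is estimated robustly from the envelope's
    lower quartile (scaled by the Rayleigh 25th percentile of a Gaussian
    background) and re-estimated after masking +/-80 ms around detected
    events, so the waves themselves do not inflate it.  Envelope peaks
    exceeding ``k`` times the background scale, separated by at least
    ``min_separation_s``, are reported with their peak times and amplitudes.
    """
    if k <= 0:
        raise InvalidParameterError("k must be positive")
    x = lfp.data[channel]
    if x.size == 0 or np.ptp(x) == 0:
        return EventList(np.array([]), np.array([]), channel, band_hz)
    lo, hi = band_hz
    pad = min(x.size, int(3 * lfp.fs / lo))
    xp = np.pad(x, pad, mode="reflect")
    xb = bandpass(xp, lo, hi, lfp.fs)
    envelope = np.abs(signal.hilbert(xb))[pad:pad + x.size]

    distance = max(1, round(min_separation_s * lfp.fs))
    half_mask = round(0.08 * lfp.fs)
    mask = np.zeros(x.size, dtype=bool)
    peaks = np.array([], dtype=int)
    heights = np.array([])
    for _ in range(max(1, n_iter)):
        background = envelope[~mask]
        # Rayleigh 25th percentile of a Gaussian background is 0.7585 sigma
        scale = np.percentile(background, 25) / 0.7585
        if scale == 0:
            return EventList(np.array([]), np.array([]), channel, band_hz)
        peaks, props = signal.find_peaks(
            envelope, height=k * scale, distance=distance
        )
        heights = props["peak_heights"]
        mask = np.zeros(x.size, dtype=bool)
        for p in peaks:
            mask[max(0, p - half_mask):p + half_mask] = True
    return EventList(
        times=peaks / lfp.fs,
        peak_amplitudes=heights,
        channel=channel,
        band_hz=band_hz,
    )


def evoked_average(
    recording: LaminarRecording,
    stim_times: np.ndarray,
    window_s: float = 0.05,
    blank_ms: float = 2.0,
) -> EvokedResponse:
    """Trial-average the post-stimulus window on every channel.

    Trials whose window extends past the recording are dropped (counted and
    logged).  Samples in the first ``blank_ms`` after the stimulus — the
    stimulation artifact — are replaced by linear interpolation between the
    average pre-stimulus sample and the first post-blank sample; ``blank_ms=0``
    returns the raw average.
    """
    stim_times = np.asarray(stim_times, dtype=float)
    n_win = round(window_s * recording.fs)
    starts = np.round(stim_times * recording.fs).astype(int)
    keep = (starts >= 0) & (starts + n_win <= recording.n_samples)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("evoked_average: dropped %d out-of-range trials", n_dropped)
    starts = starts[keep]
    if starts.size == 0:
        raise InvalidParameterError("no stimulation window fits in the recording")
    trials = np.stack([recording.data[:, s:s + n_win] for s in starts])
    avg = trials.mean(axis=0)
    if blank_ms > 0:
        nb = min(round(blank_ms / 1000.0 * recording.fs), n_win - 1)
        pre_idx = starts - 1
        pre = recording.data[:, pre_idx[pre_idx >= 0]].mean(axis=1) \
            if (pre_idx >= 0).any() else avg[:, nb]
        ramp = np.linspace(0.0, 1.0, nb + 1)[:-1]
        avg[:, :nb] = pre[:, None] + (avg[:, nb] - pre)[:, None] * ramp[None, :]
    return EvokedResponse(
        data=avg,
        fs=recording.fs,
        window_s=window_s,
        n_trials=int(starts.size),
        blank_ms=blank_ms,
        n_dropped=n_dropped,
    )
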