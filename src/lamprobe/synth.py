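"""Synthetic laminar recordings with ground truth.

Emulates the statistical structure a laminar silicon probe sees in the dorsal
hippocampus under anesthesia: a dispersed band of pyramidal-layer multiunit
spiking and a narrower granule-layer band, band-limited oscillations (theta,
gamma, ripple range) with layer-specific amplitude envelopes, sharp-wave-like
(SPW-like) transients at 2-3 Hz whose polarity flips at configured laminar
boundaries (a radiatum sink), and evoked responses to repeated stimulation
with a brief stimulation artifact.  Every stochastic element is driven by a
single seed and reported back as ground truth, so analyses can be validated by
recovery rather than by eye.

This is a phenomenological signal model, not a biophysical forward model:
components are additive, noise is white Gaussian (an optional 1/f term can be
enabled), and spike waveforms are stereotyped biphasic templates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from ._dsp import bandpass
from .morphometry import LAYER_ORDER, PIG_LAYER_WIDTHS, LayerSummaryTable
from .recording import InvalidParameterError, LaminarRecording, ProbeGeometry

__all__ = [
    "LayerMap",
    "BandEnvelope",
    "UnitSpec",
    "GeneratorConfig",
    "GroundTruth",
    "make_layer_map",
    "default_layer_map",
    "default_config",
    "simulate_recording",
    "simulate_evoked",
    "sample_layer_widths",
    "spike_template",
]


@dataclass(frozen=True)
class LayerMap:
    """Ordered laminar layers with widths and derived channel index ranges.

    ``ranges[name]`` is a half-open ``(start, stop)`` channel-index interval;
    the ranges tile ``[0, n_channels)`` dorsally to ventrally with no gaps
    (a layer narrower than the probe pitch may receive an empty range).
    """

    names: tuple[str, ...]
    widths_um: tuple[float, ...]
    pitch_um: float
    ranges: dict[str, tuple[int, int]]

    @property
    def n_channels(self) -> int:
        return math.ceil(sum(self.widths_um) / self.pitch_um)

    def channels(self, name: str) -> range:
        start, stop = self.ranges[name]
        return range(start, stop)

    def layer_of_channel(self, channel: int) -> str | None:
        for name, (start, stop) in self.ranges.items():
            if start <= channel < stop:
                return name
        return None


def make_layer_map(widths, pitch_um: float) -> LayerMap:
    """Partition a stack of layer widths into probe channel index ranges.

    ``widths`` is either a mapping ``{layer: width_um}`` (order preserved) or a
    sequence of widths taken in the canonical dorsal-to-ventral layer order.
    Each channel covers the depth interval ``[i*pitch, (i+1)*pitch)`` and is
    assigned to the layer overlapping the largest part of that interval; an
    exact tie on a shared border goes to the more dorsal (earlier) layer.
    """
    if hasattr(widths, "items"):
        names = tuple(widths.keys())
        vals = tuple(float(v) for v in widths.values())
    else:
        vals = tuple(float(v) for v in widths)
        names = LAYER_ORDER[: len(vals)]
    if pitch_um <= 0:
        raise InvalidParameterError("pitch must be positive")
    if len(vals) == 0 or any(w <= 0 for w in vals):
        raise InvalidParameterError("layer widths must be positive")

    total = sum(vals)
    n_channels = math.ceil(total / pitch_um)
    edges = np.concatenate([[0.0], np.cumsum(vals)])  # layer depth boundaries
    assignment = []
    for ch in range(n_channels):
        lo, hi = ch * pitch_um, (ch + 1) * pitch_um
        overlaps = np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo)
        assignment.append(int(np.argmax(np.round(overlaps, 9))))  # ties -> dorsal
    ranges: dict[str, tuple[int, int]] = {}
    for i, name in enumerate(names):
        chans = [ch for ch, a in enumerate(assignment) if a == i]
        if chans:
            ranges[name] = (chans[0], chans[-1] + 1)
        else:
            prev_stop = ranges[names[i - 1]][1] if i else 0
            ranges[name] = (prev_stop, prev_stop)
    return LayerMap(names=names, widths_um=vals, pitch_um=pitch_um, ranges=ranges)


def default_layer_map(probe: ProbeGeometry) -> LayerMap:
    """Pig layer widths rescaled so the seven layers tile the whole probe."""
    widths = PIG_LAYER_WIDTHS.table["mean_um"].to_numpy()
    scale = probe.n_channels * probe.pitch_um / widths.sum()
    return make_layer_map(
        dict(zip(PIG_LAYER_WIDTHS.layers, widths * scale)), probe.pitch_um
    )


@dataclass(frozen=True)
class BandEnvelope:
    """A band-limited oscillation with a per-layer amplitude envelope (µV RMS)."""

    low_hz: float
    high_hz: float
    amp_by_layer: dict[str, float]


@dataclass(frozen=True)
class UnitSpec:
    """One injected single unit: a dead-time Poisson train on one channel."""

    unit_id: int
    channel: int
    rate_hz: float
    snr: float = 10.0  # template peak amplitude in units of noise_sd
    refractory_ms: float = 2.0


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic laminar recording."""

    fs: float = 20000.0
    duration: float = 10.0
    probe: ProbeGeometry = field(default_factory=ProbeGeometry)
    layer_map: LayerMap | None = None
    band_envelopes: dict[str, BandEnvelope] | None = None
    spw_rate: float = 3.0
    spw_mode: str = "regular"  # or "poisson"
    spw_amplitude_uv: float = 100.0
    spw_sigma_ms: float = 10.0
    reversal_channels: tuple[int, int] | None = None
    units: tuple[UnitSpec, ...] | None = None
    noise_sd_uv: float = 10.0
    pink_noise_uv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.fs <= 0:
            raise InvalidParameterError("duration and sampling rate must be positive")
        if not (0.0 <= self.spw_rate <= 10.0):
            raise InvalidParameterError("spw_rate must lie in [0, 10] Hz")
        if self.spw_mode not in ("regular", "poisson"):
            raise InvalidParameterError("spw_mode must be 'regular' or 'poisson'")
        if min(self.spw_amplitude_uv, self.noise_sd_uv, self.pink_noise_uv) < 0:
            raise InvalidParameterError("amplitudes must be non-negative")
        if self.layer_map is None:
            self.layer_map = default_layer_map(self.probe)
        if self.band_envelopes is None:
            self.band_envelopes = default_band_envelopes()
        if self.reversal_channels is None:
            r0 = self.layer_map.ranges["radiatum"][0]
            m0 = self.layer_map.ranges["moleculare"][0]
            self.reversal_channels = (r0, m0)
        if self.units is None:
            self.units = default_units(self.layer_map)
        for env in self.band_envelopes.values():
            if any(a < 0 for a in env.amp_by_layer.values()):
                raise InvalidParameterError("band amplitudes must be non-negative")
            if env.high_hz >= self.fs / 2:
                raise InvalidParameterError(
                    f"band edge {env.high_hz} Hz at or above Nyquist"
                )


def default_band_envelopes() -> dict[str, BandEnvelope]:
    """Depth envelopes: theta/gamma peaking in radiatum, ripple-range power at
    the pyramidal layer (dominated there by synchronized spiking)."""
    return {
        "theta": BandEnvelope(4, 10, {
            "alveus": 1, "oriens": 2, "pyramidale": 3, "radiatum": 12,
            "lacunosum-moleculare": 4, "moleculare": 3, "granulosum": 2,
        }),
        "low_gamma": BandEnvelope(25, 55, {
            "alveus": 1, "oriens": 3, "pyramidale": 8, "radiatum": 10,
            "lacunosum-moleculare": 4, "moleculare": 3, "granulosum": 3,
        }),
        "high_gamma": BandEnvelope(55, 90, {
            "alveus": 1, "oriens": 2, "pyramidale": 6, "radiatum": 6,
            "lacunosum-moleculare": 3, "moleculare": 2, "granulosum": 2,
        }),
        "ripple": BandEnvelope(150, 250, {
            "alveus": 1, "oriens": 2, "pyramidale": 12, "radiatum": 3,
            "lacunosum-moleculare": 2, "moleculare": 2, "granulosum": 3,
        }),
    }


def default_units(layer_map: LayerMap) -> tuple[UnitSpec, ...]:
    """A dispersed cluster of pyramidal-layer units plus one granule unit."""
    pyr = list(layer_map.channels("pyramidale"))
    gran = list(layer_map.channels("granulosum"))
    specs = []
    rates = [8.0, 5.0, 10.0, 6.0, 9.0, 7.0]
    for i, rate in enumerate(rates):
        specs.append(UnitSpec(unit_id=i, channel=pyr[i % len(pyr)], rate_hz=rate))
    if gran:
        specs.append(UnitSpec(unit_id=len(specs), channel=gran[0], rate_hz=4.0))
    return tuple(specs)


def default_config(**overrides) -> GeneratorConfig:
    return GeneratorConfig(**overrides)


@dataclass
class GroundTruth:
    """Everything the generator injected, for recovery-based validation."""

    spike_times: dict[int, np.ndarray]
    spike_channels: dict[int, int]
    spw_times: np.ndarray
    reversal_boundaries: list[tuple[int, int]]
    band_envelopes: dict[str, np.ndarray]  # per-channel intended RMS, µV
    spw_polarity: np.ndarray | None = None
    evoked_template: np.ndarray | None = None  # channels x window samples, µV
    stim_times: np.ndarray | None = None


def spike_template(fs: float, amplitude_uv: float) -> np.ndarray:
    """Biphasic (negative-then-positive) ~1.2 ms extracellular spike template.

    The negative trough has magnitude ``amplitude_uv``; the trailing positive
    lobe is ~40% of it.
    """
    t = np.arange(round(1.2e-3 * fs)) / fs - 0.35e-3
    w = -np.exp(-0.5 * (t / 0.12e-3) ** 2) + 0.4 * np.exp(
        -0.5 * ((t - 0.4e-3) / 0.25e-3) ** 2
    )
    return amplitude_uv * w / np.abs(w.min())


def _dead_time_poisson(rng, rate_hz, refractory_s, duration) -> np.ndarray:
    """Poisson train with an absolute dead time; mean ISI = 1/rate exactly."""
    if rate_hz <= 0:
        return np.array([])
    mean_free = 1.0 / rate_hz - refractory_s
    if mean_free <= 0:
        raise InvalidParameterError("unit rate incompatible with refractory period")
    n_guess = int(rate_hz * duration * 2 + 20)
    isis = refractory_s + rng.exponential(mean_free, size=n_guess)
    times = np.cumsum(isis)
    while times.size and times[-1] < duration:
        extra = refractory_s + rng.exponential(mean_free, size=n_guess)
        times = np.concatenate([times, times[-1] + np.cumsum(extra)])
    return times[times < duration]


def _spw_times(rng, rate_hz, mode, duration) -> np.ndarray:
    if rate_hz <= 0:
        return np.array([])
    if mode == "regular":
        interval = 1.0 / rate_hz
        n = int(math.floor(duration / interval))
        return (np.arange(n) + 0.5) * interval
    isis = rng.exponential(1.0 / rate_hz, size=int(rate_hz * duration * 2 + 20))
    times = np.cumsum(isis)
    return times[times < duration]


def _polarity(n_channels: int, boundaries: tuple[int, int]) -> np.ndarray:
    b1, b2 = boundaries
    pol = np.ones(n_channels)
    pol[b1:b2] = -1.0
    return pol


def _add_transients(data, times, fs, waveform, channel_amps) -> None:
    """Add ``outer(channel_amps, waveform)`` centred at each event time."""
    half = len(waveform) // 2
    n = data.shape[1]
    for t in times:
        c = round(t * fs)
        lo, hi = c - half, c - half + len(waveform)
        wlo, whi = max(0, -lo), len(waveform) - max(0, hi - n)
        lo, hi = max(lo, 0), min(hi, n)
        if lo < hi:
            data[:, lo:hi] += np.outer(channel_amps, waveform[wlo:whi])


def _pink_noise(rng, shape, fs) -> np.ndarray:
    """Unit-RMS 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(shape)
    freqs = np.fft.rfftfreq(shape[-1], 1 / fs)
    scale = np.where(freqs > 1.0, 1.0 / np.sqrt(freqs), 1.0)
    x = np.fft.irfft(np.fft.rfft(white, axis=-1) * scale, n=shape[-1], axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def simulate_recording(config: GeneratorConfig) -> tuple[LaminarRecording, GroundTruth]:
    """Generate one laminar recording plus its ground truth.

    The signal is the sum of (i) white Gaussian noise, (ii) band-limited
    oscillations scaled per channel by the layer envelopes, (iii) SPW-like
    Gaussian-envelope transients whose polarity flips at the configured
    reversal boundaries, and (iv) biphasic spike templates at the ground-truth
    times on each unit's channel.  The same seed gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n_ch = config.probe.n_channels
    n_samp = round(config.duration * config.fs)
    data = rng.normal(0.0, config.noise_sd_uv, size=(n_ch, n_samp)) \
        if config.noise_sd_uv > 0 else np.zeros((n_ch, n_samp))
    if config.pink_noise_uv > 0:
        data += config.pink_noise_uv * _pink_noise(rng, (n_ch, n_samp), config.fs)

    lm = config.layer_map
    envelopes: dict[str, np.ndarray] = {}
    for name, env in config.band_envelopes.items():
        amps = np.zeros(n_ch)
        for layer, amp in env.amp_by_layer.items():
            start, stop = lm.ranges[layer]
            amps[start:stop] = amp
        envelopes[name] = amps
        if amps.any():
            carrier = rng.standard_normal(n_samp)
            carrier = bandpass(carrier, env.low_hz, env.high_hz, config.fs)
            rms = carrier.std()
            if rms > 0:
                data += np.outer(amps, carrier / rms)

    spw_times = _spw_times(rng, config.spw_rate, config.spw_mode, config.duration)
    pol = _polarity(n_ch, config.reversal_channels)
    if config.spw_amplitude_uv > 0 and spw_times.size:
        sigma = config.spw_sigma_ms / 1000.0
        t = np.arange(-4 * sigma, 4 * sigma, 1 / config.fs)
        bump = np.exp(-0.5 * (t / sigma) ** 2)
        _add_transients(data, spw_times, config.fs, bump,
                        config.spw_amplitude_uv * pol)

    spike_times: dict[int, np.ndarray] = {}
    spike_channels: dict[int, int] = {}
    for unit in config.units:
        times = _dead_time_poisson(
            rng, unit.rate_hz, unit.refractory_ms / 1000.0, config.duration
        )
        spike_times[unit.unit_id] = times
        spike_channels[unit.unit_id] = unit.channel
        if times.size:
            tmpl = spike_template(config.fs, unit.snr * max(config.noise_sd_uv, 1e-12))
            amps = np.zeros(n_ch)
            amps[unit.channel] = 1.0
            shift = (np.argmin(tmpl) - len(tmpl) // 2) / config.fs
            _add_transients(data, times - shift, config.fs, tmpl, amps)

    b1, b2 = config.reversal_channels
    truth = GroundTruth(
        spike_times=spike_times,
        spike_channels=spike_channels,
        spw_times=spw_times,
        reversal_boundaries=[(b1 - 1, b1), (b2 - 1, b2)],
        band_envelopes=envelopes,
        spw_polarity=pol,
    )
    return LaminarRecording(data=data, fs=config.fs, probe=config.probe), truth


def evoked_response_template(
    config: GeneratorConfig, window_s: float, amplitude_uv: float
) -> np.ndarray:
    """Per-channel alpha-function evoked response, sign-flipped outside radiatum.

    Negative (sink-like) within the radiatum channel range, positive above and
    below it; onset 5 ms post-stimulus, peak ~13 ms.
    """
    n_win = round(window_s * config.fs)
    t = np.arange(n_win) / config.fs
    t0, tau = 5e-3, 8e-3
    shape = np.where(t > t0, (t - t0) / tau * np.exp(1 - (t - t0) / tau), 0.0)
    r_start, r_stop = config.layer_map.ranges["radiatum"]
    pol = np.ones(config.probe.n_channels)
    pol[r_start:r_stop] = -1.0  # sink-like (negative) within radiatum
    return np.outer(amplitude_uv * pol, shape)


def simulate_evoked(
    config: GeneratorConfig,
    n_stim: int,
    isi: float,
    window: float = 0.05,
    amplitude_uv: float = 60.0,
    artifact_uv: float = 1000.0,
) -> tuple[LaminarRecording, np.ndarray, GroundTruth]:
    """Simulate a stimulation block: artifact + laminar evoked response per pulse.

    Each stimulus injects a brief (1 ms) large biphasic artifact on every
    channel followed by the per-channel response template; the response flips
    sign above and below the radiatum channel range.  Background is white
    noise at ``config.noise_sd_uv``.
    """
    if n_stim < 1:
        raise InvalidParameterError("need at least one stimulation")
    if isi <= window:
        raise InvalidParameterError("inter-stimulus interval must exceed the window")
    rng = np.random.default_rng(config.seed)
    n_ch = config.probe.n_channels
    pre = 0.25
    duration = pre + n_stim * isi
    n_samp = round(duration * config.fs)
    data = rng.normal(0.0, config.noise_sd_uv, size=(n_ch, n_samp)) \
        if config.noise_sd_uv > 0 else np.zeros((n_ch, n_samp))
    stim_times = pre + np.arange(n_stim) * isi

    # 1 ms biphasic stimulation artifact, identical on all channels
    ta = np.arange(round(1e-3 * config.fs)) / config.fs
    artifact = artifact_uv * np.sin(2 * np.pi * ta / 1e-3)

    template = evoked_response_template(config, window, amplitude_uv)
    for t in stim_times:
        i0 = round(t * config.fs)
        seg = artifact[: max(0, min(len(artifact), n_samp - i0))]
        data[:, i0:i0 + len(seg)] += seg[None, :]
        stop = min(i0 + template.shape[1], n_samp)
        data[:, i0:stop] += template[:, : stop - i0]

    r_start, r_stop = config.layer_map.ranges["radiatum"]
    truth = GroundTruth(
        spike_times={},
        spike_channels={},
        spw_times=np.array([]),
        reversal_boundaries=[(r_start - 1, r_start), (r_stop - 1, r_stop)],
        band_envelopes={},
        evoked_template=template,
        stim_times=stim_times,
    )
    rec = LaminarRecording(data=data, fs=config.fs, probe=config.probe)
    return rec, stim_times, truth


def sample_layer_widths(
    summary: LayerSummaryTable, n_subjects: int, seed: int = 0
):
    """Draw per-subject layer widths consistent with a summary table.

    Each subject's width for a layer is drawn from Normal(mean, SD) with
    SD = SEM * sqrt(n) recovered from the summary; negative draws are
    resampled (widths are physical lengths).
    """
    import pandas as pd

    if n_subjects < 1:
        raise InvalidParameterError("need at least one subject")
    if (summary.table["n"] < 2).any():
        raise InvalidParameterError("summary n must be >= 2")
    rng = np.random.default_rng(seed)
    cols = {}
    for layer, row in summary.table.iterrows():
        sd = row["sem_um"] * math.sqrt(row["n"])
        draws = rng.normal(row["mean_um"], sd, size=n_subjects)
        while (draws <= 0).any():
            bad = draws <= 0
            draws[bad] = rng.normal(row["mean_um"], sd, size=bad.sum())
        cols[layer] = draws
    df = pd.DataFrame(cols)
    df.index.name = "subject"
    return df
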