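"""Shared filtering helpers (zero-phase Butterworth band-pass)."""

from __future__ import annotations

import numpy as np
from scipy import signal

from .recording import InvalidParameterError


def butter_sos(low_hz: float | None, high_hz: float | None, fs: float, order: int = 3):
    """Design a zero-phase-ready Butterworth SOS filter.

    ``low_hz=None`` gives a low-pass, ``high_hz=None`` a high-pass.
    """
    nyq = fs / 2.0
    if high_hz is not None and high_hz >= nyq:
        raise InvalidParameterError(
            f"band edge {high_hz} Hz is at or above Nyquist ({nyq} Hz)"
        )
    if low_hz is not None and low_hz <= 0 and high_hz is None:
        raise InvalidParameterError("high-pass edge must be positive")
    if low_hz is not None and high_hz is not None:
        if low_hz >= high_hz:
            raise InvalidParameterError("band must have positive width")
        return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    if low_hz is not None:
        return signal.butter(order, low_hz, btype="highpass", fs=fs, output="sos")
    return signal.butter(order, high_hz, btype="lowpass", fs=fs, output="sos")


def bandpass(
    x: np.ndarray,
    low_hz: float,
    high_hz: float,
    fs: float,
    order: int = 3,
    pad_cycles: float = 0.0,
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass along the last axis.

    ``pad_cycles > 0`` extends the default filtfilt padding to that many
    cycles of the low band edge, suppressing edge transients for bands whose
    impulse response is long relative to the default padding.
    """
    sos = butter_sos(low_hz, high_hz, fs, order=order)
    kwargs = {}
    if pad_cycles > 0:
        kwargs["padlen"] = min(x.shape[-1] - 1, int(pad_cycles * fs / low_hz))
    return signal.sosfiltfilt(sos, x, axis=-1, **kwargs)


def mad_sigma(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Robust noise SD: median(|x|) / 0.6745 (Gaussian-consistent MAD about zero)."""
    return np.median(np.abs(x), axis=axis) / 0.6745
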