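"""Core in-memory containers for laminar multichannel recordings.

A :class:`LaminarRecording` holds a channels x time array of extracellular
voltage in microvolts together with the probe geometry that maps channel
indices to depths.  Channel 0 is the most dorsal contact; depths increase
ventrally, in micrometres below the brain surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class InvalidParameterError(ValueError):
    """Raised when an operation receives parameters outside its contract."""


@dataclass(frozen=True)
class ProbeGeometry:
    """Linear silicon-probe geometry.

    Parameters
    ----------
    n_channels
        Number of recording contacts along the shank.
    pitch_um
        Inter-contact spacing in micrometres.
    reference_offset_um
        Distance of the internal reference above the most dorsal contact.
    top_channel_depth_um
        Depth of channel 0 below the brain surface.
    """

    n_channels: int = 31
    pitch_um: float = 200.0
    reference_offset_um: float = 2000.0
    top_channel_depth_um: float = 16000.0

    def __post_init__(self) -> None:
        if self.n_channels < 3:
            raise InvalidParameterError("probe needs at least 3 channels")
        if self.pitch_um <= 0:
            raise InvalidParameterError("pitch must be positive")

    @property
    def span_um(self) -> float:
        """Distance from the first to the last contact."""
        return (self.n_channels - 1) * self.pitch_um

    def channel_depths_um(self) -> np.ndarray:
        """Depth below brain surface of every contact, dorsal to ventral."""
        return self.top_channel_depth_um + self.pitch_um * np.arange(self.n_channels)


@dataclass
class LaminarRecording:
    """Channels x time extracellular recording in microvolts."""

    data: np.ndarray
    fs: float
    probe: ProbeGeometry = field(default_factory=ProbeGeometry)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise InvalidParameterError("data must be channels x time")
        if self.fs <= 0:
            raise InvalidParameterError("sampling rate must be positive")
        if self.data.shape[0] != self.probe.n_channels:
            raise InvalidParameterError(
                f"data has {self.data.shape[0]} channels, probe declares "
                f"{self.probe.n_channels}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel_depths_um(self) -> np.ndarray:
        return self.probe.channel_depths_um()
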