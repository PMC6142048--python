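"""Shared fixtures: small seeded synthetic recordings reused across modules."""

import numpy as np
import pytest

import lamprobe as lp


@pytest.fixture(scope="session")
def mua_recording():
    """10 s, 20 kHz default recording with injected units (full generator)."""
    config = lp.GeneratorConfig(duration=10.0, fs=20000.0, seed=5)
    recording, truth = lp.simulate_recording(config)
    return config, recording, truth


@pytest.fixture(scope="session")
def lfp_recording():
    """12 s, 2 kHz recording without units, for LFP-band analyses."""
    config = lp.GeneratorConfig(duration=12.0, fs=2000.0, seed=1, units=())
    recording, truth = lp.simulate_recording(config)
    return config, recording, truth


@pytest.fixture(scope="session")
def evoked_block():
    """20-stimulation evoked block, 2 s apart, 20 kHz."""
    config = lp.GeneratorConfig(fs=20000.0, seed=4, units=())
    recording, stim_times, truth = lp.simulate_evoked(config, n_stim=20, isi=2.0)
    return config, recording, stim_times, truth


def make_recording(data, fs, pitch_um=200.0):
    """Wrap a raw array as a LaminarRecording with a matching probe.

    Rows are replicated up to the 3-channel probe minimum, so single-trace
    tests can still index channel 0.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] < 3:
        data = np.tile(data, (3, 1))[:3]
    probe = lp.ProbeGeometry(n_channels=data.shape[0], pitch_um=pitch_um)
    return lp.LaminarRecording(data=data, fs=fs, probe=probe)
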