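"""Readers, writers, and the end-to-end pipeline driver.

Recordings travel as little-endian int16 channel-interleaved flat binary plus
a JSON sidecar declaring ``n_channels``, ``sampling_rate_hz``,
``microvolts_per_bit``, ``channel_depths_um`` and ``seed``.  Tabular results
(depth profiles, event lists, unit tables, morphometry reports) are CSV with
headers at six significant digits; the run manifest is JSON.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .csd import EventList, csd_map, detect_phase_reversals, detect_spw_like, evoked_average
from .profiles import (
    BandSet,
    DepthProfile,
    band_power_profile,
    downsample,
    find_pyramidal_channel,
    mua_rms_profile,
)
from .recording import InvalidParameterError, LaminarRecording, ProbeGeometry

logger = logging.getLogger(__name__)

SIDECAR_KEYS = ("n_channels", "sampling_rate_hz", "microvolts_per_bit", "channel_depths_um")


class CorruptFileError(ValueError):
    """Binary payload inconsistent with its sidecar."""


class SchemaError(ValueError):
    """Sidecar missing a required key."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def write_recording(
    recording: LaminarRecording,
    binary_path: str | Path,
    sidecar_path: str | Path,
    seed: int | None = None,
    microvolts_per_bit: float | None = None,
) -> None:
    """Write a recording as int16-LE interleaved binary plus JSON sidecar."""
    binary_path, sidecar_path = Path(binary_path), Path(sidecar_path)
    if microvolts_per_bit is None:
        peak = float(np.abs(recording.data).max())
        microvolts_per_bit = max(peak / 32000.0, 1e-6)
    scaled = np.round(recording.data / microvolts_per_bit)
    scaled = np.clip(scaled, -32768, 32767).astype("<i2")
    scaled.T.tofile(binary_path)  # channel-interleaved: sample-major
    sidecar = {
        "n_channels": recording.n_channels,
        "sampling_rate_hz": recording.fs,
        "microvolts_per_bit": microvolts_per_bit,
        "channel_depths_um": recording.channel_depths_um().tolist(),
        "seed": seed,
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=2))


def read_recording(binary_path: str | Path, sidecar_path: str | Path) -> LaminarRecording:
    """Read an int16-LE interleaved binary recording using its JSON sidecar."""
    sidecar = json.loads(Path(sidecar_path).read_text())
    for key in SIDECAR_KEYS:
        if key not in sidecar:
            raise SchemaError(f"sidecar missing required key '{key}'")
    n_ch = int(sidecar["n_channels"])
    raw = np.fromfile(binary_path, dtype="<i2")
    if raw.size % n_ch != 0:
        raise CorruptFileError(
            f"payload of {raw.size} samples is not divisible by {n_ch} channels"
        )
    data = raw.reshape(-1, n_ch).T.astype(np.float64) * sidecar["microvolts_per_bit"]
    depths = np.asarray(sidecar["channel_depths_um"], dtype=float)
    if depths.size != n_ch:
        raise SchemaError("channel_depths_um length differs from n_channels")
    pitch = float(np.diff(depths).mean()) if n_ch > 1 else 1.0
    probe = ProbeGeometry(
        n_channels=n_ch, pitch_um=pitch, top_channel_depth_um=float(depths[0])
    )
    return LaminarRecording(data=data, fs=float(sidecar["sampling_rate_hz"]), probe=probe)


def profile_to_frame(profile: DepthProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "channel": np.arange(profile.values.size),
            "depth_um": profile.depths_um,
            "value": profile.values,
            "band": profile.band,
        }
    )


def events_to_frame(events: EventList) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_s": events.times,
            "peak_amplitude_uv": events.peak_amplitudes,
            "channel": events.channel,
        }
    )


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    """CSV writer used for all tabular outputs: 6 significant digits, no index."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g")
    return path


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    analysis_fs: float = 2000.0
    bands: BandSet = field(default_factory=BandSet)
    k_spike: float = 5.0
    k_spw: float = 4.0
    spw_band_hz: tuple[float, float] = (1.0, 20.0)
    reversal_band_hz: tuple[float, float] = (1.0, 5.0)
    seed: int = 0
    out_dir: str | Path = "lamprobe_out"
    stim_times: np.ndarray | None = None  # enables the evoked stage
    evoked_window_s: float = 0.05
    evoked_blank_ms: float = 2.0

    def __post_init__(self) -> None:
        if self.analysis_fs not in (2000.0, 3000.0):
            raise InvalidParameterError("analysis rate must be 2000 or 3000 Hz")


@dataclass
class RunManifest:
    """Record of one pipeline run: config echo, outputs, timestamps."""

    version: str
    seed: int
    config: dict
    stages: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)
    started: str = ""
    finished: str = ""
    failed_stage: str | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _check_finite(name: str, arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        raise PipelineStageError(name, "non-finite values in output")


def run_pipeline(recording: LaminarRecording, config: PipelineConfig) -> RunManifest:
    """Run the laminar localization pipeline and write all outputs.

    Stage order: downsample -> multiunit RMS profile -> pyramidal channel ->
    band-power profiles -> CSD -> phase reversals -> SPW-like events ->
    (optional) evoked average -> reports.  Any stage failure aborts with the
    stage named; outputs written so far are retained and flagged.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        seed=config.seed,
        config={
            k: (str(v) if not isinstance(v, (int, float, str, type(None))) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        started=datetime.datetime.now().isoformat(timespec="seconds"),
    )

    def stage(name):
        logger.info("pipeline stage: %s", name)
        manifest.stages.append(name)

    try:
        stage("downsample")
        lfp = downsample(recording, config.analysis_fs)
        _check_finite("downsample", lfp.data)

        stage("mua_rms_profile")
        rms = mua_rms_profile(recording)
        _check_finite("mua_rms_profile", rms.values)
        manifest.outputs["mua_rms_profile"] = str(
            write_csv(profile_to_frame(rms), out_dir / "mua_rms_profile.csv")
        )

        stage("find_pyramidal_channel")
        pyr_channel = find_pyramidal_channel(rms)

        stage("band_power_profile")
        band_profiles = band_power_profile(lfp, config.bands)
        for name, prof in band_profiles.items():
            _check_finite("band_power_profile", prof.values)
            manifest.outputs[f"band_power_{name}"] = str(
                write_csv(profile_to_frame(prof), out_dir / f"band_power_{name}.csv")
            )

        stage("csd_map")
        csd = csd_map(lfp)
        _check_finite("csd_map", csd.data)
        csd_rec = LaminarRecording(
            data=csd.data * 1e6,  # rescale for int16 quantization headroom
            fs=lfp.fs,
            probe=ProbeGeometry(
                n_channels=csd.data.shape[0],
                pitch_um=lfp.probe.pitch_um,
                top_channel_depth_um=lfp.probe.top_channel_depth_um + lfp.probe.pitch_um,
            ),
        )
        write_recording(
            csd_rec, out_dir / "csd.bin", out_dir / "csd.json", seed=config.seed
        )
        manifest.outputs["csd"] = str(out_dir / "csd.bin")

        stage("detect_phase_reversals")
        reversals = detect_phase_reversals(lfp, config.reversal_band_hz)
        manifest.outputs["phase_reversals"] = str(
            write_csv(
                pd.DataFrame(reversals, columns=["upper_channel", "lower_channel"]),
                out_dir / "phase_reversals.csv",
            )
        )

        stage("detect_spw_like")
        # SPW detection channel: theta power peaks in stratum radiatum
        spw_channel = find_pyramidal_channel(band_profiles["theta"])
        events = detect_spw_like(
            lfp, spw_channel, band_hz=config.spw_band_hz, k=config.k_spw
        )
        manifest.outputs["spw_events"] = str(
            write_csv(events_to_frame(events), out_dir / "spw_events.csv")
        )

        if config.stim_times is not None:
            stage("evoked_average")
            evoked = evoked_average(
                recording,
                config.stim_times,
                window_s=config.evoked_window_s,
                blank_ms=config.evoked_blank_ms,
            )
            _check_finite("evoked_average", evoked.data)
            evoked_rec = LaminarRecording(
                data=evoked.data, fs=recording.fs, probe=recording.probe
            )
            write_recording(
                evoked_rec, out_dir / "evoked.bin", out_dir / "evoked.json",
                seed=config.seed,
            )
            manifest.outputs["evoked"] = str(out_dir / "evoked.bin")

        stage("report")
        summary = pd.DataFrame(
            [
                {
                    "pyramidal_channel": pyr_channel,
                    "spw_channel": spw_channel,
                    "n_spw_events": events.n_events,
                    "n_reversals": len(reversals),
                }
            ]
        )
        manifest.outputs["summary"] = str(write_csv(summary, out_dir / "summary.csv"))
    except PipelineStageError:
        manifest.failed_stage = manifest.stages[-1]
        (out_dir / "manifest.json").write_text(manifest.to_json())
        raise
    except Exception as exc:
        manifest.failed_stage = manifest.stages[-1]
        (out_dir / "manifest.json").write_text(manifest.to_json())
        raise PipelineStageError(manifest.stages[-1], str(exc)) from exc

    manifest.finished = datetime.datetime.now().isoformat(timespec="seconds")
    manifest_path = out_dir / "manifest.json"
    manifest.outputs["manifest"] = str(manifest_path)
    manifest_path.write_text(manifest.to_json())
    return manifest
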