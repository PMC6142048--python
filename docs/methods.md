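# Methods

This note documents the signal model behind the synthetic generator, the
analysis algorithms and their parameters, the numerical choices made where
the design was genuinely open, and the limits of what the validation suite
can show about real recordings.

## Signal model of the synthetic generator

`simulate_recording` produces a channels × time array in microvolts as the
sum of four independent components, all driven by one `numpy` Generator
seeded from `GeneratorConfig.seed` (identical seeds give bit-identical
output):

1. **Noise** — white Gaussian, `noise_sd_uv` (default 10 µV) per sample.
   An optional 1/f-amplitude term (`pink_noise_uv`, default off) can be
   added; real extracellular noise is not characterized well enough here to
   justify it by default.
2. **Band-limited oscillations** — for each named band (theta 4–10 Hz,
   low gamma 25–55, high gamma 55–90, ripple 150–250), one shared temporal
   carrier (white noise band-passed with a zero-phase 3rd-order Butterworth,
   normalized to unit RMS) scaled per channel by a stepwise layer envelope in
   µV RMS. The default envelopes put the theta maximum in stratum radiatum
   (12 µV), gamma maxima in radiatum/pyramidale, and the ripple-range
   maximum at pyramidale (12 µV) — the depth ordering the analyses must
   recover. Theta is deliberately modest: the emulated state is isoflurane
   anesthesia, in which theta is suppressed and the low-frequency radiatum
   LFP is dominated by the 2–3 Hz SPW-like rhythm; making theta the dominant
   radiatum signal would contradict that state.
3. **SPW-like transients** — Gaussian bumps (σ = 10 ms, peak 100 µV) at
   2–3 Hz, by default *regularly* spaced at `spw_rate` = 3 Hz (one event
   every ~333 ms, matching the described "every ~300 ms" rhythm); a Poisson
   mode is available. The per-channel amplitude is +1/−1 times the peak
   according to two configured polarity boundaries (default: the start of
   the radiatum range and the start of the moleculare range, the latter
   standing in for the dentate middle molecular layer), giving a radiatum
   sink with reversals above and below.
4. **Spikes** — biphasic (negative-then-positive) ~1.2 ms templates at
   dead-time-modified Poisson times (absolute refractory period enforced
   exactly; mean rate honored exactly through the shifted-exponential ISI).
   Default units form a dispersed pyramidal-layer cluster (six units spread
   over the pyramidale channels, 5–10 Hz) plus one granule-layer unit.
   Template peak amplitude is `snr × noise_sd` (default SNR 10). The SPW
   amplitude and spike SNR are free parameters of the model — nothing in the
   emulated study quantifies them — so they were fixed once at values that
   make the events the dominant feature of their respective bands, and the
   detectors were designed against those conditions, not vice versa.

Layer geometry: `make_layer_map` tiles cumulative layer widths onto the
probe pitch; each 200-µm channel is assigned to the layer overlapping most
of its depth interval, exact ties going to the more dorsal layer, so the
channel ranges always partition the probe with no gaps. The default map
scales the pig layer-width means so the seven layers span all 31 channels.
Default sampling is 20 kHz (the 600–6000 Hz multiunit band requires
Nyquist > 6 kHz); LFP analyses run at 2 kHz after polyphase resampling.

`simulate_evoked` adds, at each of `n_stim` stimulus times, a 1-ms biphasic
~1 mV artifact on all channels followed by an alpha-function response
(onset 5 ms, peak ~13 ms, default 60 µV) that is negative (sink-like) within
the radiatum channel range and positive outside it.

## Analysis parameters

| parameter | default | rationale |
|---|---|---|
| MUA band | 600–6000 Hz, zero-phase Butterworth order 3 | field-standard multiunit band; no filter family was prescribed, Butterworth chosen for flat passband |
| wavelet high-pass | Daubechies-4, level 6, approximation zeroed | removes content below ≈ fs/2⁷ with little waveform distortion |
| spike threshold | k = 5 × σ̂, σ̂ = median(\|x\|)/0.6745, negative-going | robust MAD noise estimate; 5σ keeps the pure-noise false rate ≪ 0.2 events/s |
| spike merge | events < 1 ms apart merged, deeper trough kept | refractoriness of a single unit |
| LFP analysis rate | 2000 Hz (or 3000) | anti-aliased polyphase resampling |
| multitaper | 1-s segments, time-bandwidth 3, 5 tapers | standard resolution/variance trade-off for 1-s windows; Parseval-checked |
| band integration | trapezoid on the discrete spectrum | — |
| Welch PSD | 1-s Hann, 60% overlap, 0.2 Hz grid via 5× zero-padding, 1–20 Hz, peak-normalized | a 1-s window cannot deliver 0.2 Hz *resolution*; the stated grid is implemented as FFT spacing |
| CSD | −second spatial difference / pitch², edge channels dropped | no assumption about potentials beyond the probe; Vaknin padding available |
| phase reversal | adjacent-channel Pearson r < −0.5 on the 1–5 Hz band | reversals are identified visually in the emulated workflow; anticorrelation is the quantitative proxy |
| SPW detection | 1–20 Hz band, Hilbert envelope, k = 4 × robust background scale, ≥ 100 ms separation | see below |
| evoked window | 50 ms, artifact blank 2 ms, linear interpolation from the pre-stimulus sample | "artifact removed" implemented as blank-and-interpolate |
| autocorrelogram / ISI | ±50 ms and 0–100 ms, 1-ms bins centred on integer lags | exact symmetry about zero lag |
| rate-by-depth bins | 200 µm | matches the probe pitch and layer thickness scale |

## SPW-like event detection

Detecting individual waves of a quasi-regular 2–3 Hz rhythm is not the same
problem as detecting sparse transients. Seen through a band that only spans
the occurrence rate (e.g. 1–5 Hz), a 3 Hz train of waves collapses to its
fundamental — a continuous quasi-sinusoid whose Hilbert envelope is nearly
constant — and *no* threshold proportional to the envelope's own median can
fire on it. The detector therefore works in a band wide enough that each
wave remains a discrete transient (default 1–20 Hz; a wave lasting tens of
milliseconds has content far above 3 Hz):

1. band-pass the chosen (radiatum) channel, computing the analytic-signal
   envelope on a reflect-padded copy so filter/Hilbert end transients cannot
   masquerade as events;
2. estimate the background scale from the envelope's lower quartile, scaled
   by the Rayleigh 25th percentile (0.7585 σ) so it is calibrated on a
   Gaussian background;
3. find envelope peaks above k = 4 × scale separated by ≥ 100 ms;
4. re-estimate the scale with ±80 ms around detected events masked, and
   repeat (3 iterations) so the waves do not inflate their own threshold.

On the generator defaults this recovers the 333 ms median inter-event
interval within a few ms and ≥ 90% of injected events on average, with zero
events on pure-noise recordings. Known limitation: when rhythmic waves are
absent but an oscillatory background (theta) is present, its strongest
envelope excursions can occasionally exceed threshold (~1–3 spurious events
per 10 s); detection assumes the chosen channel actually carries the rhythm.

## Alignment and localization

`find_pyramidal_channel` is the argmax of the MUA RMS profile, ties broken
toward the most dorsal channel; an all-zero profile warns and returns
channel 0 rather than raising, since downstream per-subject loops should
survive a dead probe. `align_at_peak` shifts each subject's profile so the
peaks coincide and keeps only relative offsets covered by every subject
(n − (max peak − min peak) channels), then reports mean ± SEM across
subjects per retained channel. Aligning already-aligned profiles is a
no-op.

## Morphometry statistics

Percent differences are rounded half-away-from-zero to integers, matching
how such values are conventionally printed (the shipped pig/rat tables
reproduce 152/301/15/99/44; the rat pyramidale mean is taken as 53.12 µm,
the value consistent with the printed 301%). Welch's unequal-variance t is
reconstructed from summaries as t = Δm/√(SEM₁²+SEM₂²) with
Welch–Satterthwaite df and a two-sided p; Welch was chosen because group
sizes and variances differ, and two-sided because no directional test was
declared. No multiple-testing correction is applied across the seven layers
by default (each layer is reported as its own test); Holm–Bonferroni is
available as an option.

One caveat the package surfaces honestly: from the printed summary
statistics, radiatum gives t = 1.97, p = 0.076 two-sided (p = 0.038
one-sided) — the summary data alone do not support the published p < 0.05
call for that layer under any standard two-sample test that simultaneously
leaves oriens (t = 2.02) non-significant. The per-layer report therefore
flags four, not five, layers at α = 0.05. The published analysis presumably
used the raw per-subject widths, which are not available.

`sample_layer_widths` inverts the summaries (SD = SEM·√n, normal draws,
negative widths resampled) to generate per-subject tables for recovery
testing.

## What the validation does and does not show

The synthetic generator reproduces the *statistical structure* the analyses
assume — band-limited envelopes with known depth ordering, polarity flips at
known boundaries, known event and spike times — so passing tests demonstrate
that the implementations recover what they claim to recover at realistic
SNR. It does not emulate volume conduction or realistic CSD geometry
(components are additive per channel), electrode drift, non-stationary
states, spike-waveform diversity or overlapping units, or line noise.
Recovery rates measured here therefore bound algorithm behaviour, not
real-world yield. Spike sorting proper is out of scope: synthetic tests
assign detected events to units by nearest ground-truth time (±0.5 ms).

Problem sizes in the test and acceptance runs (2–12 s recordings, 20 kHz
for multiunit analyses, 2 kHz for LFP analyses, 20 seeded replicates for
recovery rates) were chosen as the smallest at which the measured quantities
are stable against their tolerances.

## I/O

Recordings travel as little-endian int16 channel-interleaved binary with a
JSON sidecar (`n_channels`, `sampling_rate_hz`, `microvolts_per_bit`,
`channel_depths_um`, `seed`); the quantization step is chosen per file to
span the signal's peak. Tabular outputs are CSV at six significant digits
for byte-reproducibility; each pipeline run writes a JSON manifest echoing
its configuration and listing every file produced. NWB export was left out:
the flat binary + sidecar format covers the package's own round trips, and
an NWB adapter would be a thin shim better added when a consumer needs it.
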