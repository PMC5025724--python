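"""Synthetic multichannel iEEG with known, recoverable ERD/ERS ground truth.

Each channel is a sum of

* 1/f^β background noise (spectrally shaped white noise), and
* one band-limited oscillation per frequency band, realized as band-pass
  filtered white noise so that phase is random across trials and spectra are
  broadband-realistic (event-related power changes are non-phase-locked).

An :class:`EffectSpec` multiplies the envelope of one band's oscillation by
``sqrt(power_ratio)`` inside a post-stimulus latency window on every trial,
for all channels of one (hemisphere, roi) group.  The plateau covers the full
stated window; 50 ms raised-cosine on/off ramps sit just outside it, so the
band-power ratio measured inside the window equals ``power_ratio`` (the
default background level is low enough within each band that the injected
ratio is recoverable by a direct periodogram oracle).  ERD is a ratio < 1
(power decrease), ERS a ratio > 1.  Optional
large-amplitude transient artifacts corrupt a Bernoulli fraction of epochs.
The generator returns the ground-truth artifact trials and affected channels
so downstream detection and rejection can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal

from .atlas import HEMISPHERES, ROIS, ElectrodeAtlas
from .bands import BAND_NAMES, BANDS
from .paradigm import TaskParadigm
from .preprocess import Recording

#: oscillation RMS amplitude per band, µV
DEFAULT_OSC_AMPLITUDES: dict[str, float] = {
    "theta": 2.0,
    "alpha": 6.0,
    "beta": 3.0,
    "low_gamma": 1.5,
    "high_gamma": 1.2,
}


@dataclass(frozen=True)
class EffectSpec:
    """One injected event-locked band-power change in one regional group."""

    hemisphere: str
    roi: str
    band: str
    direction: str  # 'ERD' | 'ERS'
    power_ratio: float
    window_ms: tuple[float, float] = (400.0, 600.0)

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be in {HEMISPHERES}")
        if self.roi not in ROIS:
            raise ValueError(f"roi must be in {ROIS}")
        if self.band not in BANDS:
            raise ValueError(f"band must be in {BAND_NAMES}")
        if not self.power_ratio > 0:
            raise ValueError("power_ratio must be positive")
        if self.direction == "ERD" and not self.power_ratio < 1:
            raise ValueError("ERD requires power_ratio < 1")
        if self.direction == "ERS" and not self.power_ratio > 1:
            raise ValueError("ERS requires power_ratio > 1")
        if self.direction not in ("ERD", "ERS"):
            raise ValueError("direction must be 'ERD' or 'ERS'")
        if not self.window_ms[0] < self.window_ms[1]:
            raise ValueError("effect window must have start < end")


@dataclass
class SimulationConfig:
    atlas: ElectrodeAtlas
    sampling_rate: float = 1000.0
    background_exponent: float = 2.5  # PSD ∝ 1/f^β
    background_rms: float = 5.0  # µV
    osc_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OSC_AMPLITUDES)
    )
    effects: tuple[EffectSpec, ...] = ()
    artifact_rate: float = 0.0
    artifact_amplitude: float = 150.0  # µV
    ramp_ms: float = 50.0
    # behavior on target trials: hit probability and response-time distribution
    hit_rate: float = 0.92
    rt_mean_s: float = 0.9
    rt_sd_s: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        highest = max(hi for _, hi in BANDS.values())
        if self.sampling_rate < 2 * highest:
            raise ValueError(
                f"sampling_rate must be at least twice the highest simulated "
                f"frequency ({highest} Hz)"
            )
        if not 0 <= self.artifact_rate < 1:
            raise ValueError("artifact_rate must be in [0, 1)")
        if not 0 < self.hit_rate <= 1:
            raise ValueError("hit_rate must be in (0, 1]")
        unknown = set(self.osc_amplitudes) - set(BANDS)
        if unknown:
            raise ValueError(f"unknown bands in osc_amplitudes: {sorted(unknown)}")
        self.effects = tuple(self.effects)


@dataclass
class GroundTruth:
    """What was injected: artifact trials and per-effect affected channels."""

    artifact_trials: np.ndarray
    effect_channels: list[tuple[EffectSpec, np.ndarray]]


def _one_over_f_noise(rng: np.random.Generator, n: int, exponent: float, fs: float) -> np.ndarray:
    """Unit-RMS noise with power spectral density ∝ 1/f^exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    return x / x.std()


def _band_noise(rng: np.random.Generator, n: int, sos: np.ndarray) -> np.ndarray:
    """Unit-RMS band-limited noise (band-pass filtered white noise)."""
    x = scipy.signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _effect_gain(
    n: int, onsets: np.ndarray, window_ms: tuple[float, float],
    power_ratio: float, ramp_ms: float, fs: float,
) -> np.ndarray:
    """Multiplicative envelope: sqrt(power_ratio) throughout each post-onset
    window, with raised-cosine on/off ramps of ``ramp_ms`` just outside the
    window edges (so the plateau spans the full stated window)."""
    g = np.sqrt(power_ratio)
    w0 = int(round(window_ms[0] * fs / 1000.0))
    w1 = int(round(window_ms[1] * fs / 1000.0))
    n_ramp = int(round(ramp_ms * fs / 1000.0))
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / max(n_ramp, 1)))
    profile = np.concatenate(
        [1 + (g - 1) * ramp, np.full(w1 - w0, g), g + (1 - g) * ramp]
    )
    gain = np.ones(n)
    for o in onsets:
        s = o + w0 - n_ramp
        e = min(s + len(profile), n)
        s0 = max(s, 0)
        if s0 < n:
            gain[s0:e] = profile[s0 - s : e - s]
    return gain


def simulate_recording(
    paradigm: TaskParadigm, config: SimulationConfig
) -> tuple[Recording, GroundTruth]:
    """Generate a continuous recording realizing the paradigm and effects.

    Channels are statistically independent; deterministic given
    ``config.rng_seed``.  Effect windows must fit inside the inter-stimulus
    interval.
    """
    if config.atlas.n_channels == 0:
        raise ValueError("atlas is empty")
    for eff in config.effects:
        if eff.window_ms[1] + config.ramp_ms > paradigm.isi * 1000.0:
            raise ValueError(
                f"effect window {eff.window_ms} (+{config.ramp_ms:.0f} ms ramp) "
                f"exceeds the inter-stimulus interval ({paradigm.isi * 1000:.0f} ms)"
            )
    fs = config.sampling_rate
    n_samples = int(np.ceil(paradigm.duration * fs))
    n_channels = config.atlas.n_channels
    onsets = paradigm.onsets_samples(fs)
    rng = np.random.default_rng(config.rng_seed)

    sos_bands = {
        b: scipy.signal.butter(4, BANDS[b], btype="bandpass", fs=fs, output="sos")
        for b in BAND_NAMES
    }

    # which effects touch which channel, and the shared gain envelopes
    effect_rows: list[tuple[EffectSpec, np.ndarray]] = []
    gains: dict[int, np.ndarray] = {}
    for k, eff in enumerate(config.effects):
        rows = config.atlas.channels_in(eff.hemisphere, eff.roi)
        effect_rows.append((eff, rows))
        gains[k] = _effect_gain(
            n_samples, onsets, eff.window_ms, eff.power_ratio, config.ramp_ms, fs
        )

    # artifact schedule: Bernoulli trials, each hitting 1-3 random channels
    n_trials = paradigm.n_trials
    artifact_trials = np.flatnonzero(rng.random(n_trials) < config.artifact_rate)
    artifacts_by_channel: dict[int, list[tuple[int, float]]] = {}
    pulse_len = int(round(0.1 * fs))  # 100 ms transient
    pulse = np.sin(np.pi * np.arange(pulse_len) / pulse_len) * np.sin(
        2 * np.pi * 3.0 * np.arange(pulse_len) / fs
    )
    for t in artifact_trials:
        chans = rng.choice(n_channels, size=rng.integers(1, 4), replace=False)
        # latency inside the analysis epoch (−400 … +1200 ms around onset)
        lat = int(rng.integers(-int(0.4 * fs), int(1.2 * fs)))
        start = onsets[t] + lat
        sign = 1.0 if rng.random() < 0.5 else -1.0
        for c in chans:
            artifacts_by_channel.setdefault(int(c), []).append((start, sign))

    data = np.empty((n_channels, n_samples))
    for c in range(n_channels):
        sig = config.background_rms * _one_over_f_noise(
            rng, n_samples, config.background_exponent, fs
        )
        for b in BAND_NAMES:
            amp = config.osc_amplitudes.get(b, 0.0)
            if amp == 0.0:
                continue
            trace = amp * _band_noise(rng, n_samples, sos_bands[b])
            for k, (eff, rows) in enumerate(effect_rows):
                if eff.band == b and c in rows:
                    trace = trace * gains[k]
            sig += trace
        for start, sign in artifacts_by_channel.get(c, ()):
            s = max(start, 0)
            e = min(start + pulse_len, n_samples)
            if e > s:
                sig[s:e] += sign * config.artifact_amplitude * pulse[s - start : e - start]
        data[c] = sig

    # behavior: hits and response times on target trials (misses/nontargets NaN)
    events = paradigm.to_events()
    is_target = (events["trial_type"] == "target").to_numpy()
    hit = is_target & (rng.random(n_trials) < config.hit_rate)
    rt = np.full(n_trials, np.nan)
    rt[hit] = np.maximum(
        0.2, rng.normal(config.rt_mean_s, config.rt_sd_s, size=int(hit.sum()))
    )
    events["hit"] = hit
    events["response_time"] = rt

    recording = Recording(
        data=data,
        sampling_rate=fs,
        channel_table=config.atlas,
        events=events,
        condition=paradigm.condition,
    )
    return recording, GroundTruth(
        artifact_trials=artifact_trials, effect_channels=effect_rows
    )
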