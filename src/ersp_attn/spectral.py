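"""Short-time Fourier power, per-trial ERSP, and Bonferroni significance masks.

The time–frequency decomposition follows the study design: a 500 ms sliding
Hann window with a 7.5 ms shift over a 2000 ms epoch gives 200 time bins, and
zero-padding each 500-sample segment to 1000 samples yields 1 Hz frequency
spacing, of which the 2–150 Hz range (149 bins) is retained.  The native
resolution of a 500 ms window is 2 Hz; zero-padding interpolates the spectrum
onto the 1 Hz grid without adding information.

ERSP (event-related spectral perturbation) is computed per trial as the dB
ratio of each bin's power to that trial's mean pre-stimulus baseline power at
the same frequency; a one-sample t-test across trials against 0 dB with a
Bonferroni-adjusted threshold yields the per-electrode significance mask.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.signal
import scipy.stats


@dataclass
class TimeFrequencyMap:
    """Power (µV²/Hz) or ERSP (dB) over time bins × frequency bins.

    ``values`` may carry leading trial/channel axes; the last two axes are
    always (time, frequency).  ``time_ms`` gives window-center timestamps
    relative to stimulus onset; ``window_ms`` the analysis window length.
    """

    values: np.ndarray
    time_ms: np.ndarray
    freq_hz: np.ndarray
    window_ms: float
    kind: str = "power"  # 'power' | 'dB'
    channel: str | None = None

    @property
    def n_time_bins(self) -> int:
        return self.values.shape[-2]

    @property
    def n_freq_bins(self) -> int:
        return self.values.shape[-1]


@dataclass
class SignificanceMask:
    """Signed significance of ERSP bins: +1 power increase, −1 decrease, 0 n.s.

    A bin is significant when the two-sided one-sample t-test of its
    across-trial dB values against 0 has p < alpha / n_comparisons.
    """

    mask: np.ndarray
    alpha: float
    n_comparisons: int
    t_values: np.ndarray
    p_values: np.ndarray

    @property
    def n_significant(self) -> int:
        return int(np.count_nonzero(self.mask))


def stft_power(
    signal: np.ndarray,
    sampling_rate: float = 1000.0,
    window_ms: float = 500.0,
    shift_ms: float = 7.5,
    freq_range: tuple[float, float] = (2.0, 150.0),
    freq_spacing_hz: float = 1.0,
    t0_offset_ms: float = 0.0,
    dtype=np.float64,
) -> TimeFrequencyMap:
    """Sliding-window Hann periodogram of one signal (or a batch of them).

    ``signal`` is 1-D (samples) or N-D with samples last; leading axes are
    preserved.  Window starts are the points ``k * shift_ms`` in the
    half-open interval [0, len − window); at the defaults this tiles a
    2000 ms epoch into exactly 200 bins.  A fractional shift in samples is
    rounded per start.  Each Hann-tapered segment is zero-padded to
    ``sampling_rate / freq_spacing_hz`` samples and converted to a one-sided
    power spectral density (µV²/Hz); only ``freq_range`` is retained.

    ``t0_offset_ms`` is added to the time axis, so passing the epoch's
    pre-stimulus offset (−500) yields stimulus-relative timestamps.
    ``dtype`` selects the transform precision; single precision is ample for
    power averaging across trials and roughly halves the cost.
    """
    sig = np.asarray(signal, dtype)
    fs = sampling_rate
    win = int(round(window_ms * fs / 1000.0))
    if sig.shape[-1] < win:
        raise ValueError(
            f"signal length {sig.shape[-1]} is shorter than the window ({win} samples)"
        )
    shift = shift_ms * fs / 1000.0
    span = sig.shape[-1] - win
    n_bins = max(1, math.ceil(round(span / shift, 9)))
    starts = np.round(np.arange(n_bins) * shift).astype(int)

    taper = scipy.signal.get_window("hann", win, fftbins=True)
    scale = 2.0 / (fs * np.sum(taper**2))
    taper = taper.astype(dtype)
    nfft = int(round(fs / freq_spacing_hz))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    keep = (freqs >= freq_range[0] - 1e-9) & (freqs <= freq_range[1] + 1e-9)

    idx = starts[:, None] + np.arange(win)[None, :]
    segments = sig[..., idx] * taper  # (..., n_bins, win)
    spec = np.fft.rfft(segments, n=nfft, axis=-1)
    power = scale * (spec.real**2 + spec.imag**2)

    time_ms = starts / fs * 1000.0 + window_ms / 2.0 + t0_offset_ms
    return TimeFrequencyMap(
        values=power[..., keep],
        time_ms=time_ms,
        freq_hz=freqs[keep],
        window_ms=window_ms,
        kind="power",
    )


def baseline_bins(tf: TimeFrequencyMap, baseline_ms: tuple[float, float]) -> np.ndarray:
    """Indices of time bins whose analysis window lies wholly inside the
    baseline interval (half-open)."""
    half = tf.window_ms / 2.0
    lo, hi = baseline_ms
    return np.flatnonzero(
        (tf.time_ms - half >= lo - 1e-9) & (tf.time_ms + half <= hi + 1e-9)
    )


def ersp(
    trial_maps: TimeFrequencyMap, baseline_ms: tuple[float, float] = (-500.0, 0.0)
) -> tuple[TimeFrequencyMap, TimeFrequencyMap]:
    """Per-trial dB change relative to the pre-stimulus baseline.

    ``trial_maps.values`` must be (n_trials, n_time, n_freq) raw power.  For
    every trial and frequency, dB(t, f) = 10·log10(P(t, f) / B(f)) where B(f)
    is that trial's mean power over the baseline bins.  Returns the
    trial-averaged ERSP map and the per-trial dB maps (needed for the
    t-statistic).  Normalization is single-trial, so ERSP is invariant to any
    global amplitude scaling of the signal.
    """
    if trial_maps.values.ndim != 3:
        raise ValueError("trial_maps.values must be (trials, time, freq)")
    if trial_maps.values.shape[0] < 2:
        raise ValueError("need at least 2 retained trials")
    base = baseline_bins(trial_maps, baseline_ms)
    if base.size == 0:
        raise ValueError(
            f"no time bin lies wholly inside the baseline window {baseline_ms}"
        )
    b = trial_maps.values[:, base, :].mean(axis=1, keepdims=True)
    if np.any(b <= 0):
        raise ValueError("zero baseline power: degenerate input")
    db = 10.0 * np.log10(trial_maps.values / b)
    trial_db = TimeFrequencyMap(
        values=db,
        time_ms=trial_maps.time_ms,
        freq_hz=trial_maps.freq_hz,
        window_ms=trial_maps.window_ms,
        kind="dB",
        channel=trial_maps.channel,
    )
    mean_map = TimeFrequencyMap(
        values=db.mean(axis=0),
        time_ms=trial_maps.time_ms,
        freq_hz=trial_maps.freq_hz,
        window_ms=trial_maps.window_ms,
        kind="dB",
        channel=trial_maps.channel,
    )
    return mean_map, trial_db


def significance_mask(
    trial_db: np.ndarray | TimeFrequencyMap,
    alpha: float = 0.05,
    family: int | None = None,
) -> SignificanceMask:
    """Bonferroni-corrected per-bin t-test of ERSP against 0 dB.

    ``family`` is the Bonferroni family size; by default the number of tested
    bins (per-electrode familywise control over the full 200 × 149 map).
    Bins with zero across-trial variance (e.g. the baseline bin itself, whose
    dB is identically 0) are marked non-significant with a warning.
    """
    values = trial_db.values if isinstance(trial_db, TimeFrequencyMap) else np.asarray(trial_db)
    if values.ndim < 2:
        raise ValueError("trial_db must be (trials, ...bins)")
    n_trials = values.shape[0]
    if n_trials < 10:
        raise ValueError("need at least 10 trials for the t-statistic")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    n_bins = int(np.prod(values.shape[1:]))
    if family is None:
        family = n_bins
    if family < 1:
        raise ValueError("family size must be >= 1")

    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = scipy.stats.ttest_1samp(values, 0.0, axis=0)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} bin(s) with zero across-trial variance "
            "marked non-significant",
            RuntimeWarning,
            stacklevel=2,
        )
        p = np.where(degenerate, 1.0, p)
        t = np.where(degenerate, 0.0, t)
    sig = p < alpha / family
    mask = np.where(sig, np.sign(values.mean(axis=0)), 0.0).astype(np.int8)
    return SignificanceMask(
        mask=mask, alpha=alpha, n_comparisons=int(family), t_values=t, p_values=p
    )
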