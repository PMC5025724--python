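import numpy as np
import pytest
import scipy.signal

from ersp_attn.spectral import (
    baseline_bins,
    ersp,
    significance_mask,
    stft_power,
)


def dft_power_oracle(segment, fs=1000.0, nfft=1000):
    """Brute-force zero-padded DFT periodogram of one Hann-tapered segment."""
    w = scipy.signal.get_window("hann", len(segment), fftbins=True)
    x = w * segment
    k = np.arange(nfft // 2 + 1)
    n = np.arange(len(segment))
    X = np.exp(-2j * np.pi * np.outer(k, n) / nfft) @ x
    return 2.0 * np.abs(X) ** 2 / (fs * np.sum(w**2))


class TestStftPower:
    def test_epoch_yields_200_by_149_map(self, rng):
        tf = stft_power(rng.standard_normal(2000))
        assert tf.values.shape == (200, 149)
        assert tf.freq_hz[0] == 2.0 and tf.freq_hz[-1] == 150.0
        assert np.allclose(np.diff(tf.freq_hz), 1.0)
        assert (tf.values >= 0).all()

    def test_zero_signal_zero_power(self):
        assert np.all(stft_power(np.zeros(2000)).values == 0)

    def test_sinusoid_peaks_at_its_frequency(self):
        t = np.arange(2000) / 1000.0
        tf = stft_power(np.sin(2 * np.pi * 10 * t))
        peak_freqs = tf.freq_hz[np.argmax(tf.values, axis=1)]
        assert (peak_freqs == 10.0).all()

    def test_single_segment_matches_dft_oracle(self, rng):
        seg = rng.standard_normal(500)
        tf = stft_power(seg)  # one bin: signal length == window length
        assert tf.values.shape[0] == 1
        oracle = dft_power_oracle(seg)[2:151]
        np.testing.assert_allclose(tf.values[0], oracle, rtol=1e-9)

    def test_parseval_energy_identity(self, rng):
        """Summed periodogram power equals tapered-segment energy."""
        seg = rng.standard_normal(500)
        tf = stft_power(seg, freq_range=(0.0, 500.0))
        w = scipy.signal.get_window("hann", 500, fftbins=True)
        U = np.sum(w**2)
        x2 = tf.values[0] * 1000.0 * U / 2.0  # back to |X_k|^2
        full_grid_sum = x2[0] + x2[-1] + 2 * x2[1:-1].sum()
        expected = 1000 * np.sum((w * seg) ** 2)
        np.testing.assert_allclose(full_grid_sum, expected, rtol=1e-6)

    def test_batched_leading_axes(self, rng):
        sig = rng.standard_normal((3, 2000))
        tf = stft_power(sig)
        assert tf.values.shape == (3, 200, 149)
        one = stft_power(sig[1])
        np.testing.assert_allclose(tf.values[1], one.values)

    def test_signal_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            stft_power(np.zeros(400))


class TestErsp:
    def _trials(self, rng, n=60):
        return stft_power(rng.standard_normal((n, 2000)), t0_offset_ms=-500.0)

    def test_single_baseline_bin_at_defaults(self, rng):
        tf = self._trials(rng, n=2)
        assert baseline_bins(tf, (-500.0, 0.0)).tolist() == [0]

    def test_null_ersp_near_zero(self, rng):
        _, trial_db = ersp(self._trials(rng))
        per_trial = trial_db.values.mean(axis=(1, 2))
        se = per_trial.std(ddof=1) / np.sqrt(len(per_trial))
        assert abs(per_trial.mean()) < 4 * se + 0.05

    def test_invariant_to_global_scaling(self, rng):
        sig = rng.standard_normal((10, 2000))
        _, a = ersp(stft_power(sig, t0_offset_ms=-500.0))
        _, b = ersp(stft_power(sig * 7.3, t0_offset_ms=-500.0))
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_power_doubling_gives_3db(self, rng):
        """Scaling post-baseline samples by sqrt(2) doubles power, so bins
        wholly inside the scaled region read 10*log10(2) = +3.01 dB."""
        sig = rng.standard_normal((80, 2000))
        sig[:, 500:] *= np.sqrt(2.0)
        tf = stft_power(sig)  # epoch-relative time axis
        _, trial_db = ersp(tf, baseline_ms=(0.0, 500.0))
        scaled = tf.time_ms - tf.window_ms / 2 >= 500  # window fully in scaled part
        mean_db = trial_db.values[:, scaled, :].mean()
        assert abs(mean_db - 10 * np.log10(2)) < 0.2

    def test_halving_mirrors_to_minus_3db(self, rng):
        sig = rng.standard_normal((80, 2000))
        sig[:, 500:] *= np.sqrt(0.5)
        tf = stft_power(sig)
        _, trial_db = ersp(tf, baseline_ms=(0.0, 500.0))
        scaled = tf.time_ms - tf.window_ms / 2 >= 500
        assert abs(trial_db.values[:, scaled, :].mean() + 3.0103) < 0.2

    def test_degenerate_inputs_rejected(self, rng):
        tf = self._trials(rng, n=10)
        with pytest.raises(ValueError, match="baseline"):
            ersp(tf, baseline_ms=(-3000.0, -2500.0))
        tf.values[0, 0, :] = 0.0  # kill the baseline bin of one trial
        with pytest.raises(ValueError, match="zero baseline"):
            ersp(tf)
        with pytest.raises(ValueError, match="2 retained"):
            ersp(self._trials(rng, n=2).__class__(
                values=tf.values[:1], time_ms=tf.time_ms, freq_hz=tf.freq_hz,
                window_ms=tf.window_ms))


class TestSignificanceMask:
    def test_constant_shift_all_significant_positive(self, rng):
        values = rng.normal(5.0, 0.5, size=(50, 6, 4))
        mask = significance_mask(values, alpha=0.05)
        assert (mask.mask == 1).all()

    def test_t_values_match_textbook_formula(self, rng):
        values = rng.standard_normal((12, 3, 2))
        mask = significance_mask(values)
        m = values.mean(axis=0)
        s = values.std(axis=0, ddof=1)
        np.testing.assert_allclose(mask.t_values, m / (s / np.sqrt(12)), rtol=1e-10)

    def test_count_monotone_in_family_size(self, rng):
        values = rng.normal(0.35, 1.0, size=(40, 20, 10))
        small = significance_mask(values, family=40)
        large = significance_mask(values, family=29_800)
        assert large.n_significant <= small.n_significant
        assert (np.abs(large.mask) <= np.abs(small.mask)).all()

    def test_zero_variance_bin_warns_and_is_nonsignificant(self, rng):
        values = rng.normal(3.0, 0.1, size=(20, 4))
        values[:, 2] = 0.0
        with pytest.warns(RuntimeWarning, match="zero across-trial variance"):
            mask = significance_mask(values, family=4)
        assert mask.mask[2] == 0 and (mask.mask[[0, 1, 3]] == 1).all()

    def test_parameter_validation(self, rng):
        values = rng.standard_normal((12, 4))
        with pytest.raises(ValueError, match="at least 10"):
            significance_mask(values[:5])
        with pytest.raises(ValueError, match="alpha"):
            significance_mask(values, alpha=1.5)
        with pytest.raises(ValueError, match="family"):
            significance_mask(values, family=0)
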