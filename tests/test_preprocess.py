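import numpy as np
import pandas as pd
import pytest

import ersp_attn as ea
from ersp_attn.preprocess import (
    Recording,
    bandpass,
    common_average_reference,
    epoch,
    reject_noisy_epochs,
)


def make_recording(data, fs=1000.0, onsets=(2.0,)):
    atlas = ea.default_atlas().subsample(data.shape[0])
    events = pd.DataFrame({"onset": list(onsets), "trial_type": "nontarget"})
    return Recording(data=data, sampling_rate=fs, channel_table=atlas, events=events)


class TestBandpass:
    def test_passband_tone_preserved_within_1db(self):
        t = np.arange(10_000) / 1000.0
        rec = make_recording(np.tile(np.sin(2 * np.pi * 100 * t), (3, 1)))
        out = bandpass(rec).data[0, 2000:8000]  # avoid filter edges
        gain_db = 20 * np.log10(out.std() / rec.data[0, 2000:8000].std())
        assert abs(gain_db) < 1

    def test_slow_drift_attenuated_40db(self):
        t = np.arange(40_000) / 1000.0
        rec = make_recording(np.tile(np.sin(2 * np.pi * 0.1 * t), (3, 1)))
        out = bandpass(rec).data[0]
        # FFT amplitude at 0.1 Hz before vs after
        f = np.fft.rfftfreq(len(t), 1e-3)
        k = np.argmin(np.abs(f - 0.1))
        ratio = np.abs(np.fft.rfft(out)[k]) / np.abs(np.fft.rfft(rec.data[0])[k])
        assert 20 * np.log10(ratio) < -40

    def test_zero_in_zero_out(self):
        rec = make_recording(np.zeros((3, 5000)))
        assert np.all(bandpass(rec).data == 0)

    def test_high_edge_above_nyquist_rejected(self):
        rec = make_recording(np.zeros((3, 5000)))
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(rec, 1.0, 500.0)


class TestCommonAverageReference:
    def test_per_sample_mean_is_zero(self, rng):
        rec = make_recording(rng.standard_normal((5, 4000)))
        out = common_average_reference(rec)
        assert np.allclose(out.data.mean(axis=0), 0, atol=1e-12)

    def test_three_channel_hand_example(self):
        rec = make_recording(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(
            common_average_reference(rec).data, [[-1.0], [0.0], [1.0]]
        )

    def test_identical_channels_become_zero(self):
        rec = make_recording(np.tile(np.arange(100.0), (4, 1)))
        assert np.allclose(common_average_reference(rec).data, 0)

    def test_excluded_channels_do_not_contribute(self, rng):
        rec = make_recording(rng.standard_normal((4, 200)))
        bad = rec.channel_table.channel_ids[0]
        out = common_average_reference(rec, exclude_channels=(bad,))
        assert np.allclose(out.data[1:].mean(axis=0), 0, atol=1e-12)
        assert not np.allclose(out.data.mean(axis=0), 0, atol=1e-6)

    def test_single_retained_channel_rejected(self, rng):
        rec = make_recording(rng.standard_normal((2, 100)))
        with pytest.raises(ValueError, match="at least 2"):
            common_average_reference(
                rec, exclude_channels=(rec.channel_table.channel_ids[0],)
            )

    def test_filter_and_reference_commute(self, rng):
        """Both operations are linear, so their order must not matter."""
        rec = make_recording(rng.standard_normal((4, 6000)))
        a = common_average_reference(bandpass(rec)).data
        b = bandpass(common_average_reference(rec)).data
        np.testing.assert_allclose(a, b, atol=1e-8)


class TestEpoch:
    def test_shape_and_onset_alignment(self, rng):
        data = rng.standard_normal((3, 20_000))
        rec = make_recording(data, onsets=np.arange(2.0, 18.0, 2.0))
        es = epoch(rec)
        assert es.data.shape == (8, 3, 2000)
        assert es.t0_offset_ms == -500
        # sample 500 of each epoch is the stimulus-onset sample
        np.testing.assert_array_equal(es.data[0, :, 500], data[:, 2000])

    def test_content_matches_slice_oracle(self):
        data = np.tile(np.arange(10_000.0), (2, 1))  # ramp signal
        rec = make_recording(data, onsets=(3.0,))
        es = epoch(rec)
        np.testing.assert_array_equal(es.data[0], data[:, 2500:4500])

    def test_event_at_edge_flagged_rejected(self):
        rec = make_recording(np.ones((2, 5000)), onsets=(0.0, 2.0))
        es = epoch(rec)
        assert es.rejected.tolist() == [True, False]
        assert np.all(es.data[0] == 0)  # placeholder, excluded downstream


class TestRejectNoisyEpochs:
    def _epochs(self, data):
        atlas = ea.default_atlas().subsample(data.shape[1])
        return ea.EpochSet(
            data=data, sampling_rate=1000.0, t0_offset_ms=-500.0,
            rejected=np.zeros(data.shape[0], bool),
            events=pd.DataFrame({"onset": np.arange(data.shape[0], dtype=float)}),
            channel_table=atlas,
        )

    def test_clean_data_rarely_flagged(self, null_recording):
        es = epoch(common_average_reference(bandpass(null_recording)))
        out = reject_noisy_epochs(es, amplitude_z_threshold=8.0)
        assert out.rejected.mean() <= 0.01

    def test_ground_truth_artifacts_recovered(self, erd_epochs):
        """At z = 6 at least 95% of the simulator's corrupted epochs flag."""
        epochs, truth, _ = erd_epochs
        assert epochs.rejected[truth.artifact_trials].mean() >= 0.95

    def test_flags_monotone_in_threshold(self, rng):
        data = rng.standard_normal((40, 3, 500))
        data[5, 1, 100] = 40.0
        data[9, 0, 10] = 15.0
        strict = reject_noisy_epochs(self._epochs(data), 4.0).rejected
        loose = reject_noisy_epochs(self._epochs(data), 8.0).rejected
        assert (loose <= strict).all()

    def test_infinite_threshold_flags_nothing(self, rng):
        es = self._epochs(rng.standard_normal((20, 2, 500)))
        assert reject_noisy_epochs(es, np.inf).rejected.sum() == 0

    def test_parameter_validation(self, rng):
        es = self._epochs(rng.standard_normal((20, 2, 500)))
        with pytest.raises(ValueError, match="positive"):
            reject_noisy_epochs(es, 0.0)
        with pytest.raises(ValueError, match="at least 10"):
            reject_noisy_epochs(self._epochs(rng.standard_normal((5, 2, 500))), 6.0)
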