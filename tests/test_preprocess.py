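"""Preprocessing contracts: CAR, notch, exclusion, IED rejection, envelope."""

import numpy as np
import pytest
import warnings

from prespeech.preprocess import (
    EnvelopeDataset,
    PreprocessConfig,
    baseline_normalize,
    common_average_reference,
    detect_ied_trials,
    exclude_bad_channels,
    hg_envelope,
    notch_filter,
    preprocess_dataset,
    robust_background,
)
from prespeech.synthgen import ChannelInfo, SynthConfig, generate_dataset, inject_ied

FS = 1000.0


def tone(freq, n=4000, amp=1.0, fs=FS):
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestCommonAverageReference:
    def test_zero_mean_after(self, rng):
        x = rng.standard_normal((4, 6, 500))
        good = np.array([True] * 6)
        out = common_average_reference(x, good)
        np.testing.assert_allclose(out[:, good, :].mean(axis=1), 0.0, atol=1e-12)

    def test_uses_good_channels_only(self, rng):
        x = rng.standard_normal((2, 4, 100))
        good = np.array([True, True, False, True])
        out = common_average_reference(x, good)
        np.testing.assert_allclose(out[:, good, :].mean(axis=1), 0.0, atol=1e-12)
        # bad channel still referenced against the good mean
        np.testing.assert_allclose(
            out[:, 2, :], x[:, 2, :] - x[:, good, :].mean(axis=1), atol=1e-12
        )

    def test_needs_two_good(self, rng):
        with pytest.raises(ValueError):
            common_average_reference(rng.standard_normal((1, 3, 50)),
                                     np.array([True, False, False]))


class TestNotch:
    def test_60hz_attenuated_20db(self):
        x = tone(60.0)[None, None, :]
        y = notch_filter(x, FS, (60.0,))
        mid = slice(1000, 3000)
        ratio = np.abs(y[0, 0, mid]).max() / np.abs(x[0, 0, mid]).max()
        assert 20 * np.log10(ratio) <= -20.0

    def test_passband_preserved(self):
        x = tone(100.0)[None, None, :]
        y = notch_filter(x, FS, (60.0, 120.0, 180.0))
        mid = slice(1000, 3000)
        ratio = np.abs(y[0, 0, mid]).max() / np.abs(x[0, 0, mid]).max()
        assert ratio > 0.9

    def test_nyquist_guard(self):
        with pytest.raises(ValueError):
            notch_filter(tone(60.0)[None, None, :], FS, (600.0,))


class TestExclusion:
    def _ch(self, cid, imp, bad=False):
        return ChannelInfo(cid, "s1", "L", 9, imp, is_bad=bad)

    def test_strictly_greater_excluded(self):
        chans = [self._ch("a", 10.0), self._ch("b", 10.0001), self._ch("c", 3.0)]
        assert exclude_bad_channels(chans, 10.0) == ["a", "c"]

    def test_is_bad_excluded(self):
        chans = [self._ch("a", 5.0, bad=True), self._ch("b", 5.0)]
        assert exclude_bad_channels(chans, 10.0) == ["b"]

    def test_negative_impedance_rejected(self):
        with pytest.raises(ValueError):
            exclude_bad_channels([self._ch("a", -1.0)])


class TestRobustBackground:
    def test_matches_mad_oracle(self, rng):
        x = rng.standard_normal((8, 1100))
        times = -400.0 + np.arange(1100)
        base = x[:, (times >= -300.0) & (times < 0.0)]
        med = np.median(base)
        expected = 1.4826 * np.median(np.abs(base - med))
        assert robust_background(x, times) == pytest.approx(expected)

    def test_scale_equivariance(self, rng):
        x = rng.standard_normal((4, 1100))
        times = -400.0 + np.arange(1100)
        assert robust_background(3.0 * x, times) == pytest.approx(
            3.0 * robust_background(x, times)
        )


@pytest.fixture(scope="module")
def ied_raw():
    cfg = SynthConfig(
        n_subjects=1, areas=((9, "L"),), channels_per_area=5,
        n_trials=20, n_body=10, impedance_high_rate=0.0,
        epoch_start_ms=-400.0, epoch_end_ms=700.0, seed=77,
    )
    return generate_dataset(cfg)


class TestIedDetection:
    def test_clean_data_not_flagged(self, ied_raw):
        flags = detect_ied_trials(ied_raw.signals, FS, ied_raw.times_ms)
        assert flags.sum() == 0

    def test_3x_60ms_flagged(self, ied_raw):
        ds = inject_ied(ied_raw, ied_raw.trials[0].trial_id,
                        ied_raw.channels[0].channel_id, 3.0, 60.0)
        flags = detect_ied_trials(ds.signals, FS, ds.times_ms)
        assert flags[0] and flags.sum() == 1

    def test_3x_5ms_not_flagged(self, ied_raw):
        ds = inject_ied(ied_raw, ied_raw.trials[0].trial_id,
                        ied_raw.channels[0].channel_id, 3.0, 5.0)
        flags = detect_ied_trials(ds.signals, FS, ds.times_ms)
        assert flags.sum() == 0

    def test_run_length_window(self, rng):
        # a sustained 300 ms elevation is outside the 20-200 ms IED range;
        # the same elevation lasting 100 ms is inside it
        times = -400.0 + np.arange(1100)
        for dur_ms, expect in ((300, False), (100, True)):
            x = rng.standard_normal((11, 1, 1100))
            x[0, 0, 500:500 + dur_ms] += 8.0
            flags = detect_ied_trials(x, FS, times)
            assert bool(flags[0]) is expect
            assert flags[1:].sum() == 0


class TestEnvelope:
    def test_unit_tone_contract(self):
        x = tone(100.0)[None, None, :]
        env = hg_envelope(x, FS)
        assert abs(env[0, 0, 500:3500].mean() - 1.0) <= 0.05

    def test_wavelet_unit_tone_contract(self):
        x = tone(100.0)[None, None, :]
        env = hg_envelope(x, FS, method="wavelet")
        assert abs(env[0, 0, 500:3500].mean() - 1.0) <= 0.05

    def test_out_of_band_suppressed(self):
        env = hg_envelope(tone(10.0)[None, None, :], FS)
        assert env[0, 0, 500:3500].mean() < 0.05

    def test_nonnegative(self, rng):
        env = hg_envelope(rng.standard_normal((2, 3, 1000)), FS)
        assert (env >= 0).all()

    def test_amplitude_linear(self):
        e1 = hg_envelope(tone(100.0)[None, None, :], FS)
        e2 = hg_envelope(tone(100.0, amp=2.5)[None, None, :], FS)
        np.testing.assert_allclose(e2, 2.5 * e1, rtol=1e-8)

    def test_bad_method(self):
        with pytest.raises(ValueError):
            hg_envelope(np.zeros((1, 1, 100)), FS, method="fft")

    def test_bad_band(self):
        with pytest.raises(ValueError):
            hg_envelope(np.zeros((1, 1, 100)), FS, hg_band=(70.0, 600.0))


class TestBaselineNormalize:
    def test_baseline_z_units(self, rng):
        times = -400.0 + np.arange(1100)
        env = np.abs(rng.standard_normal((12, 3, 1100))) + 1.0
        out, _ = baseline_normalize(env, times)
        base = out[:, :, (times >= -300.0) & (times < 0.0)]
        np.testing.assert_allclose(base.mean(axis=(0, 2)), 0.0, atol=1e-10)
        np.testing.assert_allclose(base.std(axis=(0, 2)), 1.0, atol=1e-10)

    def test_rejected_trials_excluded_from_stats(self, rng):
        times = -400.0 + np.arange(1100)
        env = np.abs(rng.standard_normal((12, 2, 1100))) + 1.0
        spoiled = env.copy()
        spoiled[0] += 100.0  # a rejected artifact trial must not shift stats
        rej = np.zeros(12, dtype=bool)
        rej[0] = True
        out_clean, _ = baseline_normalize(env[1:], times)
        out_masked, _ = baseline_normalize(spoiled, times, rejected_trials=rej)
        np.testing.assert_allclose(out_masked[1:], out_clean, atol=1e-10)

    def test_per_trial_mode(self, rng):
        times = -400.0 + np.arange(1100)
        env = np.abs(rng.standard_normal((6, 2, 1100))) + 1.0
        out, _ = baseline_normalize(env, times, per_trial=True)
        base = out[:, :, (times >= -300.0) & (times < 0.0)]
        np.testing.assert_allclose(base.mean(axis=2), 0.0, atol=1e-10)
        np.testing.assert_allclose(base.std(axis=2), 1.0, atol=1e-10)


class TestPreprocessDataset:
    def test_output_types(self, small_env, small_raw):
        assert isinstance(small_env, EnvelopeDataset)
        assert small_env.envelope.shape[0] == small_raw.signals.shape[0]
        assert small_env.envelope.shape[2] == small_raw.signals.shape[2]
        assert (small_env.envelope.shape[1] <= small_raw.signals.shape[1])

    def test_high_impedance_dropped(self):
        cfg = SynthConfig(
            n_subjects=1, areas=((9, "L"),), channels_per_area=8,
            n_trials=12, n_body=6, impedance_high_rate=0.5,
            epoch_start_ms=-400.0, epoch_end_ms=700.0, seed=31,
        )
        ds = generate_dataset(cfg)
        n_high = sum(c.impedance_kohm > 10.0 for c in ds.channels)
        assert n_high > 0  # the config did produce high-impedance channels
        env = preprocess_dataset(ds, PreprocessConfig())
        assert len(env.channels) == len(ds.channels) - n_high
        assert all(c.impedance_kohm <= 10.0 for c in env.channels)

    def test_rejected_frame_shape(self, small_env, small_raw):
        assert list(small_env.rejected.index) == small_raw.subject_ids
        assert list(small_env.rejected.columns) == list(small_raw.word_ids)

    def test_planted_effect_visible_in_z_units(self, small_env, small_raw):
        """The d=2.0 planted effect survives preprocessing with d > 0.5."""
        t = small_env.times_ms
        win = (t >= 150.0) & (t < 250.0)
        idx = [i for i, c in enumerate(small_env.channels) if c.brodmann_area == 9]
        feat = small_env.envelope[:, idx][:, :, win].mean(axis=(1, 2))
        y = small_env.word_categories == "body"
        sp = np.sqrt((feat[y].var(ddof=1) + feat[~y].var(ddof=1)) / 2)
        assert (feat[y].mean() - feat[~y].mean()) / sp > 0.5

    def test_deterministic(self, small_raw):
        a = preprocess_dataset(small_raw, PreprocessConfig())
        b = preprocess_dataset(small_raw, PreprocessConfig())
        np.testing.assert_array_equal(a.envelope, b.envelope)
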