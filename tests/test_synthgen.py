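"""Generator ground-truth: shapes, determinism, planted-quantity fidelity."""

import numpy as np
import pytest
import scipy.signal as sps

from prespeech.synthgen import (
    PlantedCoupling,
    PlantedEffect,
    SynthConfig,
    generate_dataset,
    inject_ied,
    sample_speech_onsets,
)


def rectified_envelope(signals, sample_rate, cutoff_hz=10.0):
    """Independent envelope oracle: rectify then low-pass."""
    sos = sps.butter(4, cutoff_hz, btype="low", fs=sample_rate, output="sos")
    return sps.sosfiltfilt(sos, np.abs(signals), axis=-1)


def cohens_d(a, b):
    sp = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    return (a.mean() - b.mean()) / sp


def clean_carrier_config(**kw):
    """Config whose signals are the bare gain-modulated carrier."""
    base = dict(
        background_amp=0.0,
        line_noise_amp=(0.0, 0.0, 0.0),
        impedance_high_rate=0.0,
        epoch_start_ms=-400.0,
        epoch_end_ms=700.0,
    )
    base.update(kw)
    return SynthConfig(**base)


class TestShapesAndMetadata:
    def test_shapes(self, small_raw, small_config):
        cfg = small_config
        n_ch = len(cfg.areas) * cfg.channels_per_area * cfg.n_subjects
        n_samp = int(
            (cfg.epoch_end_ms - cfg.epoch_start_ms) * cfg.sample_rate / 1000.0
        )
        assert small_raw.signals.shape == (cfg.n_trials, n_ch, n_samp)
        assert len(small_raw.channels) == n_ch
        # one TrialInfo per subject and word
        assert len(small_raw.trials) == cfg.n_subjects * cfg.n_trials

    def test_word_alignment(self, small_raw):
        # the trials axis indexes the shared word list
        assert len(small_raw.word_ids) == small_raw.signals.shape[0]
        assert set(small_raw.word_categories) == {"body", "nonbody"}

    def test_category_balance(self, small_raw, small_config):
        n_body = int((small_raw.word_categories == "body").sum())
        assert n_body == small_config.n_body

    def test_times(self, small_raw, small_config):
        t = small_raw.times_ms
        assert t[0] == small_config.epoch_start_ms
        assert t[-1] < small_config.epoch_end_ms

    def test_determinism(self, small_config, small_raw):
        again = generate_dataset(small_config)
        np.testing.assert_array_equal(again.signals, small_raw.signals)
        assert [c.channel_id for c in again.channels] == [
            c.channel_id for c in small_raw.channels
        ]

    def test_seed_changes_data(self, small_config):
        from dataclasses import replace

        other = generate_dataset(replace(small_config, seed=999))
        assert not np.array_equal(
            other.signals, generate_dataset(small_config).signals
        )


class TestValidation:
    def test_bad_band(self):
        with pytest.raises(ValueError):
            SynthConfig(hg_band=(170.0, 70.0)).validate()

    def test_nyquist(self):
        with pytest.raises(ValueError):
            SynthConfig(sample_rate=300.0).validate()

    def test_bad_counts(self):
        with pytest.raises(ValueError):
            SynthConfig(n_trials=0).validate()
        with pytest.raises(ValueError):
            SynthConfig(n_body=99).validate()

    def test_unknown_area(self):
        with pytest.raises(ValueError):
            SynthConfig(areas=((123, "L"),)).validate()

    def test_bad_target_r2(self):
        cfg = SynthConfig(
            areas=((22, "L"), (39, "L")),
            couplings=(PlantedCoupling(22, "L", 39, "L", 3, 6, 1.5),),
        )
        with pytest.raises(ValueError):
            generate_dataset(cfg)


class TestSpeechOnsets:
    def test_floor(self):
        on = sample_speech_onsets(5000, seed=1)
        assert on.min() >= 500.0
        # mean of the truncated normal stays near the nominal mean
        assert abs(on.mean() - 881.0) < 30.0

    def test_degenerate_sd(self):
        np.testing.assert_array_equal(
            sample_speech_onsets(10, seed=0, sd_ms=0.0), np.full(10, 881.0)
        )

    def test_bad_n(self):
        with pytest.raises(ValueError):
            sample_speech_onsets(0, seed=0)

    def test_deterministic(self):
        np.testing.assert_array_equal(
            sample_speech_onsets(50, seed=3), sample_speech_onsets(50, seed=3)
        )


class TestPlantedQuantities:
    def test_null_effect_size(self):
        """No planted effects: pooled |d| of window-mean envelope < 0.2."""
        cfg = clean_carrier_config(
            n_subjects=1, areas=((9, "L"),), channels_per_area=5,
            n_trials=200, n_body=100, seed=7,
        )
        ds = generate_dataset(cfg)
        env = rectified_envelope(ds.signals, cfg.sample_rate)
        t = ds.times_ms
        win = (t >= 0.0) & (t < 100.0)
        feat = env[:, :, win].mean(axis=-1)
        y = ds.word_categories == "body"
        d = cohens_d(feat[y].mean(axis=1), feat[~y].mean(axis=1))
        assert abs(d) < 0.2

    def test_planted_d_oracle(self):
        """Planted d=2.0, 0-100 ms: carrier-envelope Cohen's d in 2.0 +/- 0.4.

        Oracle: direct rectify+low-pass envelope extraction on the generated
        carrier (noise terms disabled; the gain fields are config-determined).
        """
        ds_means = []
        for seed in (1, 7, 42):
            cfg = clean_carrier_config(
                n_subjects=1, areas=((9, "L"),), channels_per_area=5,
                n_trials=200, n_body=100,
                effects=(PlantedEffect(9, "L", 0.0, 100.0, 2.0),), seed=seed,
            )
            ds = generate_dataset(cfg)
            env = rectified_envelope(ds.signals, cfg.sample_rate)
            t = ds.times_ms
            win = (t >= 0.0) & (t < 100.0)
            feat = env[:, :, win].mean(axis=-1)
            y = ds.word_categories == "body"
            per_ch = [cohens_d(feat[y, c], feat[~y, c]) for c in range(feat.shape[1])]
            ds_means.append(np.mean(per_ch))
        for d in ds_means:
            assert 1.6 <= d <= 2.4, ds_means

    def test_effect_confined_to_window(self):
        """The planted gain difference is absent outside its time window."""
        cfg = clean_carrier_config(
            n_subjects=1, areas=((9, "L"),), channels_per_area=5,
            n_trials=200, n_body=100,
            effects=(PlantedEffect(9, "L", 150.0, 250.0, 2.0),), seed=11,
        )
        ds = generate_dataset(cfg)
        env = rectified_envelope(ds.signals, cfg.sample_rate)
        t = ds.times_ms
        far = (t >= 400.0) & (t < 500.0)  # windows 9-10, disjoint segments
        feat = env[:, :, far].mean(axis=-1)
        y = ds.word_categories == "body"
        d = cohens_d(feat[y].mean(axis=1), feat[~y].mean(axis=1))
        assert abs(d) < 0.3

    def test_gain_level_coupling_r2(self):
        """Planted target_r2: window-mean gain R^2 within rho^2 +/- 0.12."""
        for seed in (5000, 5001, 5002):
            cfg = clean_carrier_config(
                n_subjects=1, areas=((22, "L"), (39, "L")), channels_per_area=10,
                n_trials=400, n_body=200,
                couplings=(PlantedCoupling(22, "L", 39, "L", 3, 6, 0.5),),
                seed=seed,
            )
            ds = generate_dataset(cfg)
            env = rectified_envelope(ds.signals, cfg.sample_rate)
            t = ds.times_ms
            w3 = (t >= 100.0) & (t < 200.0)
            w6 = (t >= 250.0) & (t < 350.0)
            src = [i for i, c in enumerate(ds.channels) if c.brodmann_area == 22]
            tgt = [i for i, c in enumerate(ds.channels) if c.brodmann_area == 39]
            s = env[:, src][:, :, w3].mean(axis=(1, 2))
            g = env[:, tgt][:, :, w6].mean(axis=(1, 2))
            r2 = np.corrcoef(s, g)[0, 1] ** 2
            assert 0.38 <= r2 <= 0.62, (seed, r2)

    def test_line_noise_present(self, small_raw, small_config):
        f, p = sps.welch(small_raw.signals[0, 0], fs=small_config.sample_rate, nperseg=1024)
        peak = p[np.argmin(np.abs(f - 60.0))]
        neighborhood = p[(np.abs(f - 60.0) > 5) & (np.abs(f - 60.0) < 15)].mean()
        assert peak > 10 * neighborhood


class TestInjectIed:
    def test_ground_truth_recorded(self, small_raw):
        ds = inject_ied(small_raw, small_raw.trials[0].trial_id,
                        small_raw.channels[0].channel_id, 3.0, 60.0)
        assert len(ds.injected_ieds) == len(small_raw.injected_ieds) + 1
        # the source dataset is untouched by default
        assert ds is not small_raw

    def test_amplitude_scales_with_background(self, small_raw):
        ds = inject_ied(small_raw, small_raw.trials[0].trial_id,
                        small_raw.channels[0].channel_id, 3.0, 60.0)
        diff = np.abs(ds.signals - small_raw.signals)
        assert diff.max() > 0
        # only one (trial, channel) touched
        touched = np.argwhere(diff.max(axis=-1) > 0)
        assert len(touched) == 1
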