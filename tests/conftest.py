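"""Shared fixtures: one small dataset run through the full preprocessing."""

import numpy as np
import pytest

from prespeech.features import WindowGrid, window_features
from prespeech.preprocess import PreprocessConfig, preprocess_dataset
from prespeech.synthgen import PlantedEffect, SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(
        n_subjects=2,
        areas=((9, "L"), (22, "L")),
        channels_per_area=3,
        n_trials=20,
        n_body=10,
        epoch_start_ms=-400.0,
        epoch_end_ms=700.0,
        impedance_high_rate=0.0,
        effects=(PlantedEffect(9, "L", 150.0, 250.0, 2.0),),
        seed=12345,
    )


@pytest.fixture(scope="session")
def small_raw(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_env(small_raw):
    return preprocess_dataset(small_raw, PreprocessConfig())


@pytest.fixture(scope="session")
def small_features(small_env):
    return window_features(small_env, WindowGrid())


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
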