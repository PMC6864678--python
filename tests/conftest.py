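import numpy as np
import pytest

import teafluor as tf
from teafluor.synthetic import (
    BAND_CHL_FAR_RED,
    BAND_CHL_RED,
    BAND_GREEN_ORANGE,
    FluorophoreBand,
    NoiseModel,
    TeaClassProfile,
)


@pytest.fixture(scope="session")
def grid():
    return tf.default_grid()


@pytest.fixture(scope="session")
def leds():
    return tf.default_led_profiles()


@pytest.fixture(scope="session")
def profiles():
    return tf.default_class_profiles()


@pytest.fixture
def quiet_noise():
    """No detector noise, no background, no excitation-light leakage."""
    return NoiseModel(additive_sd=0.0, background_level=0.0, led_reflection=0.0)


def make_profile(
    label="TEST",
    go_amp=0.3,
    red_amp=1.0,
    fr_amp=0.7,
    cv=0.0,
    go_center=550.0,
    red_center=680.0,
    fr_center=740.0,
    jitter=0.0,
    width_cv=0.0,
):
    """Deterministic single-class profile with uniform excitation efficiency."""
    ones = tuple(1.0 for _ in range(7))
    return TeaClassProfile(
        label=label,
        bands=(
            FluorophoreBand(BAND_GREEN_ORANGE, go_center, 35.0),
            FluorophoreBand(BAND_CHL_RED, red_center, 10.0),
            FluorophoreBand(BAND_CHL_FAR_RED, fr_center, 16.0),
        ),
        band_mean_amplitude={
            BAND_GREEN_ORANGE: go_amp,
            BAND_CHL_RED: red_amp,
            BAND_CHL_FAR_RED: fr_amp,
        },
        band_cv={BAND_GREEN_ORANGE: cv, BAND_CHL_RED: cv, BAND_CHL_FAR_RED: cv},
        excitation_efficiency={
            BAND_GREEN_ORANGE: ones,
            BAND_CHL_RED: ones,
            BAND_CHL_FAR_RED: ones,
        },
        peak_jitter_sd_nm=jitter,
        width_cv=width_cv,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Six measurements per class in the calibrated regime."""
    return tf.generate_dataset(6, seed=42)


@pytest.fixture(scope="session")
def small_matrices(small_dataset):
    return [tf.preprocess_measurement(r) for r in small_dataset]


@pytest.fixture(scope="session")
def small_split(small_matrices):
    return tf.split_dataset(small_matrices, seed=7)
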