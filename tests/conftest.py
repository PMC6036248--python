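import numpy as np
import pytest

from eegdrift.features import BandScheme
from eegdrift.synthetic import generate_feature_study, make_model

BAND_NAMES = ["delta", "theta", "alpha", "beta", "low_gamma", "high_gamma"]


def band_feature(channel: int, band: int) -> str:
    """Feature column name for 0-based (channel, band) indices."""
    return f"CH{channel + 1}_{BAND_NAMES[band]}"


@pytest.fixture(scope="session")
def bands():
    return BandScheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def small_model(**kwargs):
    """A fast 4-channel model with two informative pairs; override freely."""
    defaults = dict(
        n_channels=4,
        informative=[(0, 2), (1, 4)],
        class_effect_scale=0.6,
        day_effect_sd=0.0,
        noise_sd=0.15,
        epochs_per_day_per_class=(20,) * 5,
        seed=0,
    )
    defaults.update(kwargs)
    return make_model(**defaults)


@pytest.fixture()
def separable_study():
    """Strong class effect on every feature, no drift, low noise: every
    protocol should max out.  (After per-feature z-scoring, uninformative
    features contribute unit-variance noise to kernel distances no matter how
    small the raw noise is, so full separability needs signal everywhere.)"""
    model = small_model(
        informative=[(c, b) for c in range(4) for b in range(6)],
        class_effect_scale=1.5,
        noise_sd=0.05,
    )
    return generate_feature_study(model, "S1")


@pytest.fixture()
def chance_study():
    """No class effect at all: labels carry no information."""
    model = small_model(informative=[], class_effect_scale=0.0, noise_sd=0.2, seed=7)
    return generate_feature_study(model, "S1")
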