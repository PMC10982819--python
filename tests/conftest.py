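"""Shared fixtures: small synthetic cohorts and a quickly trained model.

Everything is generated programmatically at test time; heavy objects are
session-scoped so the suite trains networks only once per configuration.
"""

import numpy as np
import pytest

from wisdom import (
    CohortParams,
    WisdomConfig,
    generate_cohort,
    train_intensity_model,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Feature-rich cohort of 40 bags with clear metastatic signal."""
    return generate_cohort(CohortParams.strong_signal(n_patients=40, seed=77))


@pytest.fixture(scope="session")
def feature_cohort():
    """Feature-only cohort (no rendered patches), 300 bags, default effects."""
    return generate_cohort(CohortParams(n_patients=300, render_patches=False, seed=5))


@pytest.fixture(scope="session")
def quick_model(small_cohort):
    """An intensity model trained briefly on the small strong-signal cohort.

    Short schedule: enough for scores to become non-degenerate, cheap
    enough for the unit-test suite.
    """
    cfg = WisdomConfig(epochs=4, batch_bags=16, val_fraction=0.0, seed=3)
    return train_intensity_model(small_cohort[:30], cfg)
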