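import numpy as np
import pytest

import pulsedx as px


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n=70, calibrated overlap), seed 0."""
    labels, mats = px.simulate_amplitude_cohort(px.CohortSpec(seed=0))
    return labels, mats


@pytest.fixture(scope="session")
def default_features(default_cohort):
    labels, mats = default_cohort
    return px.feature_table(mats, labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
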