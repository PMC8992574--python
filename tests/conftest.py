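"""Shared fixtures: noise-free Drunk Incense campaign artifacts."""

import numpy as np
import pytest

from graperipe import maturity, synthetic


@pytest.fixture(scope="session")
def di_archetype():
    return synthetic.DEFAULT_ARCHETYPES["drunk_incense"]


@pytest.fixture(scope="session")
def di_clean_series(di_archetype):
    weeks = synthetic.default_weeks(di_archetype)
    cfg = synthetic.TrajectoryConfig(weeks=weeks, noise_sd=0.0, seed=0)
    return synthetic.generate_indicator_series(di_archetype, cfg)


@pytest.fixture(scope="session")
def di_timeline(di_clean_series):
    return maturity.construct_mc_timeline(di_clean_series)


@pytest.fixture(scope="session")
def di_clean_color(di_archetype, di_timeline):
    cfg = synthetic.TrajectoryConfig(weeks=tuple(float(w) for w in di_timeline.weeks),
                                     noise_sd=0.0, seed=0)
    return synthetic.generate_color_series(di_archetype, di_timeline, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
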