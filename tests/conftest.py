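import logging

import numpy as np
import pytest

import inflammadx as ix

logging.getLogger("inflammadx").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def schema():
    return ix.DEFAULT_SCHEMA


@pytest.fixture(scope="session")
def default_cohort():
    """One seed-fixed synthetic cohort with the published class sizes."""
    return ix.generate_cohort(ix.default_config(), seed=1)


@pytest.fixture(scope="session")
def fitted_model(default_cohort):
    return ix.fit_two_step(default_cohort, seed=1)


@pytest.fixture
def make_cohort(schema):
    """Build a small valid cohort from a feature-dict and labels."""

    def _make(n, labels=None, rng_seed=0, overrides=None):
        rng = np.random.default_rng(rng_seed)
        X = np.abs(rng.normal(5.0, 1.0, size=(n, 18)))
        # keep percentage columns within range
        for i, f in enumerate(schema.features):
            if f.is_percentage:
                X[:, i] = np.clip(X[:, i], 0, 100)
        if overrides:
            for name, col in overrides.items():
                X[:, schema.index_of(name)] = col
        if labels is None:
            labels = [ix.CONTROL] * n
        return ix.CohortTable.from_arrays(X, labels, schema=schema)

    return _make
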