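"""Shared fixtures.

The trained torque models are session-scoped because training is the
expensive step; the small model is adequate wherever only qualitative
behaviour (sign conventions, zero point) matters, while the full-size
model backs the quantitative recovery checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from hybridgait.cnn import CnnTorqueRegressor, train
from hybridgait.reference import default_envelope_model, default_reference_table
from hybridgait.synth import gen_isometric_dataset


@pytest.fixture(scope="session")
def reference_table():
    return default_reference_table()


@pytest.fixture(scope="session")
def envelope_models():
    return {
        "TA": default_envelope_model("TA"),
        "soleus": default_envelope_model("soleus"),
    }


@pytest.fixture(scope="session")
def small_dataset():
    return gen_isometric_dataset(n_samples=600, seed=7)


@pytest.fixture(scope="session")
def small_model(small_dataset):
    """Quickly trained torque model for qualitative checks."""
    model = CnnTorqueRegressor(max_epochs=15, patience=10, seed=0)
    model, metrics = train(model, small_dataset)
    model.train_metrics_ = metrics
    return model


@pytest.fixture(scope="session")
def full_dataset():
    """The reference synthetic isometric dataset (n=2000, seed=7)."""
    return gen_isometric_dataset(n_samples=2000, seed=7)


@pytest.fixture(scope="session")
def full_model(full_dataset):
    model = CnnTorqueRegressor(max_epochs=120, patience=10, seed=0)
    model, metrics = train(model, full_dataset)
    model.train_metrics_ = metrics
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(1)
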