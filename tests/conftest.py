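import numpy as np
import pandas as pd
import pytest

import metsfnn as m
from metsfnn.fnn import TrainingConfig


@pytest.fixture(scope="session")
def small_cohort():
    """One seeded default cohort with labels, shared across tests."""
    spec = m.original_spec(n_subjects=2000, seed=7)
    baseline, followup = m.generate_cohort(spec)
    labels = m.assign_cohort_labels(baseline, followup)
    return spec, baseline, followup, labels


@pytest.fixture(scope="session")
def toy_separable():
    """1-D linearly separable toy set: cases at x>1, controls at x<-1."""
    rng = np.random.default_rng(42)
    x = np.concatenate([rng.uniform(1, 3, 100), rng.uniform(-3, -1, 100)])
    t = np.concatenate([np.ones(100), -np.ones(100)])
    return pd.DataFrame({"x": x}), t


@pytest.fixture(scope="session")
def toy_interaction():
    """2-D set where the outcome requires both inputs high."""
    rng = np.random.default_rng(43)
    a, b = rng.normal(0, 1, 400), rng.normal(0, 1, 400)
    t = np.where((a > 0.3) & (b > 0.3), 1.0, -1.0)
    return pd.DataFrame({"a": a, "b": b}), t


@pytest.fixture()
def fast_config():
    return TrainingConfig(epochs=200)
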