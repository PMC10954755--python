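import numpy as np
import pytest

from readthru.features import attach_negative_controls, default_schema, extract_feature_table
from readthru.forest import ModelSpec, train_regressor
from readthru.simulate import SimConfig, simulate_catalog, strong_signal_config


@pytest.fixture(scope="session")
def full_schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_sim(full_schema):
    """A 300-transcript default-condition catalog with features and truth."""
    config = SimConfig(n_transcripts=300, seed=42)
    records, truth = simulate_catalog(config)
    table, excluded = extract_feature_table(records, full_schema)
    assert not excluded
    table = attach_negative_controls(table, seed=42)
    return {"config": config, "records": records, "truth": truth, "features": table}


@pytest.fixture(scope="session")
def strong_sim(full_schema):
    """A 600-transcript strong-signal catalog (model-behaviour tests)."""
    config = strong_signal_config(seed=7)
    config.n_transcripts = 600
    records, truth = simulate_catalog(config)
    table, _ = extract_feature_table(records, full_schema)
    table = attach_negative_controls(table, seed=7)
    return {"config": config, "records": records, "truth": truth, "features": table}


@pytest.fixture(scope="session")
def tiny_regressor(strong_sim, full_schema):
    """A quick untuned forest for prediction-contract tests."""
    spec = ModelSpec(task="regression", n_trees=30, seed=11, tune=False)
    return train_regressor(
        strong_sim["features"], strong_sim["truth"]["true_log2_re"].to_numpy(),
        spec, full_schema,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240320)
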