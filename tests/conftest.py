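import numpy as np
import pytest

from oilknn import knn_core, oilgen, pipeline


@pytest.fixture(scope="session")
def dataset():
    """The default synthetic dataset at seed 1 (shared, read-only)."""
    return oilgen.generate(oilgen.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def split_data(dataset):
    return oilgen.split(dataset, 0.6, seed=1)


@pytest.fixture(scope="session")
def fitted_rom(split_data):
    """600-entry ROM on the deployed 4-feature set, seed 1."""
    train, _ = split_data
    feats = pipeline.DEPLOYED_FEATURES
    X = train[list(feats)].to_numpy(dtype=float)
    y = train["label"].to_numpy(dtype=int)
    params = knn_core.fit_quantizer(X, feats)
    return knn_core.build_rom(X, y, params, seed=1)


@pytest.fixture(scope="session")
def test_queries(split_data):
    """Held-out real-valued query matrix and labels on the deployed features."""
    _, test = split_data
    X = test[list(pipeline.DEPLOYED_FEATURES)].to_numpy(dtype=float)
    y = test["label"].to_numpy(dtype=int)
    return X, y
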