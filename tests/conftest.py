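import numpy as np
import pytest

from hemonam import (FeatureTable, NAMClassifier, NAMConfig, TrainConfig,
                     default_hematology_spec, generate_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """n=600 default cohort, shared across read-only tests."""
    spec = default_hematology_spec(seed=11, n=600)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_table():
    rng = np.random.default_rng(5)
    x = rng.normal(size=(40, 3))
    y = (x[:, 0] + rng.normal(scale=0.5, size=40) > 0).astype(int)
    return FeatureTable(x, ["a", "b", "c"], y)


@pytest.fixture(scope="session")
def fitted_small(small_cohort):
    """A quick fit on the small cohort (reduced epochs) for API-level tests."""
    table, gt = small_cohort
    cfg = TrainConfig(max_epochs=30, seed=11)
    res = NAMClassifier(table, nam_config=NAMConfig(hidden_sizes=(16, 8)),
                        train_config=cfg).fit(split_seed=11, seed=11)
    return res, gt
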