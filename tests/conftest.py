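import numpy as np
import pytest

import axialseg as ax


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def phantom_pair():
    """One small synthetic case (volume, labels)."""
    cfg = ax.phantom.small_phantom_config(seed=11)
    return ax.generate_phantom(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """Twenty small synthetic cases: 16 for training, 4 held out."""
    return ax.generate_cases(20, ax.phantom.small_phantom_config(), seed=123)


@pytest.fixture(scope="session")
def tiny_config():
    return ax.tiny_train_config(seed=7, max_epoch=10, iters_per_epoch=25)


@pytest.fixture(scope="session")
def trained_tiny(small_cohort, tiny_config):
    """Model trained on the 16 training phantoms of the small cohort.

    Session-scoped: training dominates the suite's runtime, so every test
    needing a trained model shares this one.
    """
    result = ax.train_fold(small_cohort[:16], tiny_config,
                           val_cases=small_cohort[16:])
    return result
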