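import numpy as np
import pytest

from evidentomics import SyntheticConfig, generate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 3-class, 3-modality dataset with clear signal."""
    cfg = SyntheticConfig(n_samples=120, n_classes=3,
                          features_per_modality=(40, 40, 20),
                          effect_size=2.0, seed=5)
    ds, truth = generate(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def survival_dataset():
    """Small dataset with class-dependent exponential survival."""
    from evidentomics import SurvivalConfig
    cfg = SyntheticConfig(n_samples=150, n_classes=2,
                          features_per_modality=(30, 30, 15),
                          effect_size=2.5, seed=21,
                          survival=SurvivalConfig(base_hazard=0.1,
                                                  class_hazard_ratios=(1.0, 3.0),
                                                  censoring_rate=0.2))
    ds, truth = generate(cfg)
    return ds, truth
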