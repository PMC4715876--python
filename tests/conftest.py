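import warnings

import numpy as np
import pytest

from adhd_cea.config import ConfigWarning, ModelConfig, ModelSettings, load_base_case


@pytest.fixture()
def base_config() -> ModelConfig:
    """Base-case configuration (published model inputs).

    Loading renormalizes the combined-GXR Severe row (raw sum 0.911) with a
    warning, which is expected and silenced here.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConfigWarning)
        return load_base_case()


@pytest.fixture()
def settings() -> ModelSettings:
    return ModelSettings()


@pytest.fixture()
def identity_config(base_config: ModelConfig) -> ModelConfig:
    """Base config with identity transition matrices in both arms."""
    config = base_config.copy()
    for arm in config.arms.values():
        arm.transitions.p = np.eye(4)
        arm.transitions.raw = np.eye(4)
        arm.transitions.se = np.zeros((4, 4))
    return config


def random_stochastic_matrix(rng: np.random.Generator) -> np.ndarray:
    m = rng.random((4, 4)) + 1e-3
    return m / m.sum(axis=1, keepdims=True)
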