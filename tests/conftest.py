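import numpy as np
import pytest

from grouphawk import ModelConfig


@pytest.fixture
def baseline_config() -> ModelConfig:
    """Standard worked example: leaders mildly advantaged in both the cost
    and benefit splits (d = 0.55), 30% leaders, groups of 100, C = 2V."""
    return ModelConfig(
        omega=0.4, epsilon=0.3, n_group=100,
        v_total=1.0, c_total=2.0, d_v=0.55, d_c=0.55,
    )


@pytest.fixture
def symmetric_config() -> ModelConfig:
    """Equal sharing: both classes prefer the classic Hawk-Dove ESS V/C."""
    return ModelConfig(
        omega=0.4, epsilon=0.3, n_group=100,
        v_total=1.0, c_total=2.0, d_v=0.5, d_c=0.5,
    )


@pytest.fixture
def follower_advantaged_config() -> ModelConfig:
    """d < 0.5 favours followers: the 'democratic war' direction."""
    return ModelConfig(
        omega=0.4, epsilon=0.3, n_group=100,
        v_total=1.0, c_total=2.0, d_v=0.45, d_c=0.45,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
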