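import numpy as np
import pytest

from enrichtest import DesignSpec, EffectScenario

SEED = 1  # single fixed seed for every stochastic test


@pytest.fixture
def design_b0() -> DesignSpec:
    """Flagship configuration: equal prevalence, full alpha both tests, b=0."""
    return DesignSpec(150, 150, alpha_s=0.025, alpha_o=0.025, b=0.0, k=0.59)


@pytest.fixture
def design_b0_normal(design_b0) -> DesignSpec:
    """Same configuration under the large-sample critical-value convention."""
    import dataclasses

    return dataclasses.replace(design_b0, critical_scale="normal")


@pytest.fixture
def scenario_null() -> EffectScenario:
    return EffectScenario(0.0, 0.0, 1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(SEED)
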