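import numpy as np
import pytest

from fingerkick.simulate import EffectConfig, simulate_parameter_table


@pytest.fixture(scope="session")
def study_table():
    """One seeded parameter table at the study design (21 participants)."""
    table, truth = simulate_parameter_table(EffectConfig(seed=123))
    return table, truth


@pytest.fixture(scope="session")
def small_config():
    """Reduced design for fast pipeline and property tests."""
    return EffectConfig(n_preschool=3, n_school=4, trials_per_condition=3, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
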