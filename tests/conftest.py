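import numpy as np
import pytest

from srnaspike import design, workflows


@pytest.fixture(scope="session")
def default_sets():
    """The SRQC + ERDN sets designed with default constraints (shared)."""
    return workflows.design_sets(seed=0)


@pytest.fixture(scope="session")
def srqc_set(default_sets):
    return default_sets[0]


@pytest.fixture(scope="session")
def erdn_set(default_sets):
    return default_sets[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def constraints():
    return design.DesignConstraints()
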