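import numpy as np
import pytest

from scarmech.simulate import SimulationSpec


@pytest.fixture
def base_spec() -> SimulationSpec:
    """Small, fast default simulation spec for unit tests."""
    return SimulationSpec(seed=42, n_proteins=200)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
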