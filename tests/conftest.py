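import numpy as np
import pytest

from autozyg.simulate import SimulationConfig


@pytest.fixture
def small_cfg() -> SimulationConfig:
    """A fast two-chromosome cohort used across module tests."""
    return SimulationConfig(
        n_samples=24,
        chrom_lengths=(("chr1", 15_000_000), ("chr2", 15_000_000)),
        inbred_fraction=0.25,
        seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
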