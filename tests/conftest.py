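import numpy as np
import pytest

from eladkit.simulate import SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def world():
    """Default 20-Mb planted world shared by the recovery tests."""
    genome, truth = simulate_genome(SimulationConfig(), seed=1)
    return genome, truth


@pytest.fixture(scope="session")
def small_config():
    """A 6-Mb world for fast end-to-end runs."""
    return SimulationConfig(
        chromosomes=(("chr1", 6_000_000),),
        n_genes=240,
        n_elads=5,
        clad_fraction=0.15,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
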