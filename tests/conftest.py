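import numpy as np
import pytest

from ecckit import (
    SimulationConfig,
    generate_reference,
    sample_true_circles,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=7, n_chroms=2, chrom_length=200_000, n_circles=60)


@pytest.fixture(scope="session")
def small_reference(small_config):
    return generate_reference(small_config)


@pytest.fixture(scope="session")
def small_study(small_config):
    """Genome, annotations, planted circles and reads for one small sample.

    Built on its own genome copy since motif planting mutates the reference.
    """
    genome, annotations = generate_reference(small_config)
    circles = sample_true_circles(small_config, genome, annotations)
    reads = simulate_reads(circles, genome, small_config)
    return genome, annotations, circles, reads


@pytest.fixture
def rng():
    return np.random.default_rng(42)
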