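import numpy as np
import pytest

from edmakit.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def default_experiment():
    """The full-size synthetic experiment the package is validated under:
    20,000 probes, 200 planted DMRs of |dM| = 2, 4 dye-swap pairs, seed 42."""
    return simulate_experiment(SimConfig(seed=42))


@pytest.fixture(scope="session")
def small_experiment():
    """A fast, reduced experiment for pipeline plumbing tests."""
    config = SimConfig(
        seed=7,
        n_chromosomes=1,
        chromosome_length=400_000,
        n_islands_per_chromosome=20,
        n_genes_per_chromosome=10,
        n_repeats_per_chromosome=30,
        n_probes=1_200,
        n_dmrs=40,
        genomic_control_spacing=20_000,
    )
    return simulate_experiment(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
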