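import numpy as np
import pytest

from poegp import popsim


@pytest.fixture(scope="session")
def small_population():
    """A small but structured population shared across test modules."""
    cfg = popsim.SimConfig(
        n_chrom=2, snps_per_chrom=60, n_qtl=12,
        founder_males=25, founder_females=25,
        hist_generations=80, recent_generations=3, recent_size=120,
        seed=42,
    )
    return popsim.simulate_population(cfg)


@pytest.fixture(scope="session")
def small_export(small_population):
    pop = small_population
    return popsim.export_dataset(pop, pop.generations_present())


@pytest.fixture()
def rng():
    return np.random.default_rng(20160418)
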