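import warnings

import numpy as np
import pytest

from upcycle import genome_sim as gs
from upcycle.scheme import SimConfig, run_burnin


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_map():
    """Two chromosomes, 60 evenly spaced chip loci each, no QTL."""
    n = 120
    chrom = np.repeat(np.arange(2, dtype=np.int32), 60)
    cm = np.tile(np.linspace(0.0, 100.0, 60), 2)
    gmap = gs.GeneticMap(chrom, cm, np.ones(n, bool), np.zeros(n, bool), 2, 100.0)
    return gmap


@pytest.fixture(scope="session")
def tiny_config():
    return SimConfig(
        n_chromosomes=5,
        n_loci=1000,
        n_qtl=200,
        chip_size=300,
        n_dams=40,
        litter_size=6,
        n_burnin=3,
        burnin_sires=6,
        vce_sample=200,
        max_doses=8,
        n_founders=160,
        history_generations=15,
        history_ne=60,
        full_metrics_from=-99,
    )


@pytest.fixture(scope="session")
def burned_state(tiny_config):
    """A shared post-burn-in state; tests must clone() before mutating."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_burnin(tiny_config, seed=2024)
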