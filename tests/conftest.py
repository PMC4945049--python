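import numpy as np
import pytest

from plasmacnv.genome import hg19_genome, toy_genome
from plasmacnv.simulate import SimulationConfig, simulate_sample


@pytest.fixture(scope="session")
def toy_model():
    """Small 5-chromosome genome (430 Mb, 4300 bins at 100 kb)."""
    return toy_genome(bin_size=100_000, seed=0)


@pytest.fixture(scope="session")
def hg19_model():
    """Full 24-chromosome hg19-scale genome (~31k bins at 100 kb)."""
    return hg19_genome(bin_size=100_000, seed=0)


# toy-genome read depth matching the study's ~226 reads per 100 kb bin
TOY_READS = 1_000_000


def simulate(model, seed=0, **kwargs):
    kwargs.setdefault("total_reads",
                      TOY_READS if model.n_bins < 10_000 else 7_000_000)
    cfg = SimulationConfig(seed=seed, **kwargs)
    cov, truth, f = simulate_sample(model, cfg)
    return cov, truth, f
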