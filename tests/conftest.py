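import numpy as np
import pytest

from breedsim.config import RunConfig
from breedsim.founders import GenomeParams, simulate_founders
from breedsim.genetics import base_cohort
from breedsim.genome import GenomeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_params():
    """A small but complete genome: enough loci and drift for every class."""
    return GenomeParams(
        n_chromosomes=3, loci_per_chromosome=150, chromosome_length=1.0,
        mutation_rate=2e-5,
        historical_trajectory=((80, 120), (20, 15), (50, 15)),
        base_males=60, base_females=60, n_qtl=40, n_neutral=40)


@pytest.fixture(scope="session")
def tiny_founders(tiny_params):
    return simulate_founders(tiny_params, seed=20240)


@pytest.fixture(scope="session")
def tiny_base(tiny_founders):
    return base_cohort(tiny_founders)


@pytest.fixture
def grid_small():
    return GenomeGrid.create(n_chromosomes=2, loci_per_chromosome=50)


def micro_config(**overrides) -> RunConfig:
    """A minutes-free breeding-program configuration for orchestration tests."""
    base = {
        "genome": {"n_chromosomes": 3, "loci_per_chromosome": 100,
                   "historical_trajectory": [{"size": 60, "generations": 60},
                                              {"size": 16, "generations": 8},
                                              {"size": 40, "generations": 8}],
                   "n_qtl": 30, "n_neutral": 30,
                   "base_males": 50, "base_females": 50},
        "program": {"n_sires_pblup": 10, "n_sires_ocs": 4, "generations": 8},
        "evaluation": {"window_generations": 4, "n_genotyped_males": 20,
                       "always_gblup": True},
        "metrics": {"n_kinship_pairs": 150},
    }
    for key, val in overrides.items():
        if isinstance(val, dict):
            base.setdefault(key, {}).update(val)
        else:
            base[key] = val
    return RunConfig.model_validate(base)


@pytest.fixture(scope="session")
def micro_cfg():
    return micro_config()


@pytest.fixture(scope="session")
def micro_founders(micro_cfg):
    return simulate_founders(GenomeParams.from_config(micro_cfg), seed=77)
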