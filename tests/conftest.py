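import numpy as np
import pytest

from somabench.core import MixtureSpec
from somabench.pipeline import (
    PipelineConfig,
    build_genomes,
    simulate_sample,
    simulate_truth,
)


@pytest.fixture(scope="session")
def fixture_config() -> PipelineConfig:
    """Desk-scale study conditions shared by the slower end-to-end tests."""
    return PipelineConfig(
        seed=11,
        genome_length=100_000,
        n_targets=20,
        target_length=500,
        n_clones=8,
        n_somatic=200,
        n_germline=400,
        depth=50.0,
        normal_depth=50.0,
        kappa=0.2,
    )


@pytest.fixture(scope="session")
def sim(fixture_config):
    return simulate_truth(fixture_config)


@pytest.fixture(scope="session")
def genomes(sim, fixture_config):
    return build_genomes(sim, seed=fixture_config.seed)


@pytest.fixture(scope="session")
def sample_pools(sim, genomes, fixture_config):
    mixture = MixtureSpec(
        kappa=fixture_config.kappa,
        coverage_level=fixture_config.depth,
        seed=fixture_config.seed,
    )
    return simulate_sample(sim, genomes, mixture, fixture_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
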