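import numpy as np
import pytest

from translatome.pipeline import PipelineResult, run_pipeline
from translatome.synthetic_data import SimConfig, generate_genome


@pytest.fixture(scope="session")
def default_pipeline() -> PipelineResult:
    """One full run on the default synthetic experiment (2000 genes, seed 1)."""
    return run_pipeline(SimConfig(n_genes=2000, seed=1))


@pytest.fixture(scope="session")
def small_genome():
    """A small synthetic genome for structural tests (300 genes, seed 7)."""
    cfg = SimConfig(n_genes=300, seed=7, n_footprints=30_000)
    models, genome, truth = generate_genome(cfg)
    return cfg, models, genome, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
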