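"""Shared fixtures: small synthetic worlds reused across test modules."""

from __future__ import annotations

import pytest

from ipaseq import SimConfig, build_toy_world
from ipaseq.pipeline import run_synthetic_pipeline


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_genes=30, reads_per_library=5000, seed=1)


@pytest.fixture(scope="session")
def small_world(small_config):
    genome, models, truth = build_toy_world(small_config)
    return small_config, genome, models, truth


@pytest.fixture(scope="session")
def small_run(small_config):
    """Full pipeline on the small world (30 genes, 4 x 5000 reads)."""
    return run_synthetic_pipeline(small_config, rnaseq_depth=20_000)


@pytest.fixture(scope="session")
def default_run():
    """The default synthetic study: 200 genes, 2 conditions x 2 replicates x
    50,000 reads plus knockdown libraries, RNA-seq depth 100,000/condition."""
    config = SimConfig(seed=7, include_knockdown=True)
    return run_synthetic_pipeline(config, rnaseq_depth=100_000)
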