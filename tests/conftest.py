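import dataclasses

import pytest

from epspec import pipeline
from epspec.config import PipelineConfig
from epspec.synth import SimConfig

TINY = SimConfig(
    n_chrom=2,
    chrom_length_bp=8_000_000,
    n_enhancers=120,
    n_tss=30,
    n_tf=12,
    n_tf_clusters=3,
    seed=7,
)


def tiny_sim_config(**overrides) -> SimConfig:
    return dataclasses.replace(TINY, **overrides)


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    return tiny_sim_config()


@pytest.fixture(scope="session")
def tiny_sim(tiny_config):
    """A small simulated study (~1000 candidate pairs), shared read-only."""
    return pipeline.simulate_dataset(tiny_sim_config())


@pytest.fixture(scope="session")
def tiny_pipeline_config() -> PipelineConfig:
    return PipelineConfig(holdout_chroms=("chr2",))


@pytest.fixture(scope="session")
def tiny_features(tiny_sim, tiny_pipeline_config):
    """Assembled feature matrix for the tiny study (with NMF columns)."""
    return pipeline.build_feature_matrix(
        tiny_sim.ep,
        tiny_sim.elements,
        tiny_sim.contacts,
        tf_presence=tiny_sim.tf_presence,
        config=tiny_pipeline_config,
    )


@pytest.fixture(scope="session")
def tiny_labeled(tiny_sim, tiny_features):
    """(ep, labels, feature matrix) restricted to labeled rows."""
    return pipeline.labeled_view(tiny_features, tiny_sim.ep)
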