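import numpy as np
import pytest

import dropfuse as df
from dropfuse.fusion import FusionConfig, PipelineConfig
from dropfuse.vgae import VGAEConfig


@pytest.fixture(scope="session")
def tiny_fixture():
    """Tiny simulated dataset (50 x 30, 2 clusters) for unit tests."""
    spec = df.fixture_suite()["tiny"]
    X, labels, means, tech = df.generate_counts(spec)
    return {"spec": spec, "X": X, "labels": labels, "means": means,
            "tech_mask": tech}


@pytest.fixture(scope="session")
def medium_fixture():
    """Medium simulated dataset (2000 x 500, 4 clusters, ~80% sparsity)."""
    spec = df.fixture_suite()["medium"]
    X, labels, means, tech = df.generate_counts(spec)
    return {"spec": spec, "X": X, "labels": labels, "means": means,
            "tech_mask": tech}


def tiny_pipeline_config(seed: int = 0) -> PipelineConfig:
    """Seconds-scale pipeline configuration for the tiny fixture."""
    return PipelineConfig(
        n_top_genes=None, group_size=25, k_min=2, k_max=4,
        pca_components=10, n_neighbors=5,
        vgae=VGAEConfig(hidden_dim=16, latent_dim=4, epochs=30),
        fusion=FusionConfig(hidden_layers=(16,), epochs=30,
                            min_train_entries=20),
        nmf_rank=4, nmf_max_iter=200).reseeded(seed)


def medium_pipeline_config(seed: int = 0) -> PipelineConfig:
    """Minutes-scale configuration for the medium fixture.

    Depth is reduced relative to library defaults (50 VGAE epochs, 32
    hidden units, k searched over 4..8, capped fusion training set) to
    keep end-to-end runs fast at 2000 x 500 scale.
    """
    return PipelineConfig(
        k_min=4, k_max=8,
        vgae=VGAEConfig(hidden_dim=32, latent_dim=16, epochs=50),
        fusion=FusionConfig(hidden_layers=(64,), epochs=40,
                            max_train_entries=15000),
        nmf_max_iter=500).reseeded(seed)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
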