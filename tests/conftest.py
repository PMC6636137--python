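"""Shared fixtures: synthetic worlds reused across test modules.

All fixtures are generated programmatically from fixed seeds; there are no
stored data files.
"""

from __future__ import annotations

import numpy as np
import pytest

import mosqsub as m

STUDY_SEED = 11


def make_study_samples(theta: float = 5.0, edge_bias: float = 0.8, seed: int = STUDY_SEED):
    """The 23-sample study world: clustered allocation, noisy biometrics."""
    config = m.ExperimentConfig(
        clustering=m.ClusteringModel(theta=theta, edge_bias=edge_bias), seed=seed
    )
    return m.simulate_samples(config)


@pytest.fixture(scope="session")
def study_samples():
    return make_study_samples()


@pytest.fixture(scope="session")
def uniform_samples():
    """23 samples with effectively uniform multinomial allocation."""
    return make_study_samples(theta=1e6, edge_bias=1.0)


@pytest.fixture(scope="session")
def toy4():
    """4-cell, single-species toy universe with counts {4, 6, 10, 20}."""
    return m.GriddedSample.from_counts(np.array([[4], [6], [10], [20]]), sample_id="toy4")


@pytest.fixture(scope="session")
def disjoint_images():
    """10 noise-free sheet photos with non-overlapping blobs and exact truth."""
    render = m.RenderParams(noise_sd=0.0, allow_overlap=False, size_cv=0.15)
    images = []
    for i in range(10):
        comp = m.generate_composition(
            4, 50 + 12 * i, dominance=0.5, seed=100 + i, sample_id=f"img{i}"
        )
        gridded = m.allocate_to_grid(comp, m.ClusteringModel(theta=30.0), seed=200 + i)
        images.append(m.render_sheet_image(gridded, render, seed=300 + i))
    return images
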