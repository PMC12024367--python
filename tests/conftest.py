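"""Shared fixtures: a small, fast synthetic cohort and toy encoder configs.

The small cohort uses a narrowed 900-1800 cm^-1 grid (226 points) that still
covers the protein amide and carbohydrate bands, with 12/8/8 subjects, so
training-loop tests run in seconds.  Full-size (1801-point, 36/24/24) runs
live in the acceptance tests.
"""

import numpy as np
import pytest

import spectrafuse as sf
from spectrafuse.data_model import WavenumberGrid
from spectrafuse.synthetic import CohortConfig


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(
        n_positive_subjects=12,
        n_other_subjects=8,
        n_healthy_subjects=8,
        samples_per_subject=(2, 3),
        replicates_per_sample=3,
        grid=WavenumberGrid(900.0, 1800.0, 4.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return sf.generate_cohort(small_config)


@pytest.fixture(scope="session")
def split_small_cohort(small_cohort):
    return sf.grouped_split(small_cohort, seed=5)


@pytest.fixture(scope="session")
def small_enc_config(small_config) -> sf.EncoderConfig:
    return sf.EncoderConfig(
        d_ftir=small_config.grid.n_points, d_chem=36, seed=3
    )


@pytest.fixture(scope="session")
def fast_train_config() -> sf.TrainConfig:
    return sf.TrainConfig(batch_size=32, epochs=6, seed=3)


@pytest.fixture(scope="session")
def small_state(split_small_cohort, small_enc_config, fast_train_config):
    """One trained fused encoder on the small cohort, shared across tests."""
    return sf.train(split_small_cohort, small_enc_config, fast_train_config,
                    "both")


@pytest.fixture(scope="session")
def toy_enc_config() -> sf.EncoderConfig:
    """Tiny architecture for exact numeric checks and gradient tests."""
    return sf.EncoderConfig(d_ftir=6, d_chem=3, d1=4, d2=2, n_heads=2, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
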