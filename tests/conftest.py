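"""Shared fixtures: small phantom cohorts and their derived assets.

Everything is generated programmatically at fixture time; grids are kept
small (tens of thousands of voxels at most) so the suite stays fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from datnorm.phantom import PhantomConfig, archetypes, generate_phantom
from datnorm.pipeline import cohort_assets


def small_config(**overrides) -> PhantomConfig:
    """A 29x29x19 phantom with defaults scaled from the canonical grid."""
    params = dict(
        shape=(29, 29, 19),
        n_nc=6,
        n_ps=6,
        psf_sigma=1.5 * 29 / 73,
        seed=11,
    )
    params.update(overrides)
    return PhantomConfig(**params)


@pytest.fixture(scope="session")
def phantom_config():
    return small_config()


@pytest.fixture(scope="session")
def phantom_cohort(phantom_config):
    cohort, truth = generate_phantom(phantom_config)
    return cohort, truth


@pytest.fixture(scope="session")
def phantom_archetypes(phantom_config):
    return archetypes(phantom_config)


@pytest.fixture(scope="session")
def phantom_assets(phantom_cohort):
    """(template, masks) derived from the small phantom cohort."""
    cohort, _ = phantom_cohort
    return cohort_assets(cohort)


@pytest.fixture(scope="session")
def noiseless_config():
    """Corrupted but noise- and jitter-free: affine effects are exact."""
    return small_config(noise_sigma=0.0, subject_uptake_sd=0.0, seed=21)


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_config):
    return generate_phantom(noiseless_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
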