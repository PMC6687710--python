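"""Shared fixtures: small synthetic cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sccproteo.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(
        n_tumors=20,
        n_plexes=6,
        n_proteins=600,
        n_genes=600,
        program_size=60,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """Small cohort with no biological or measurement noise: batch effects
    (plex shifts, channel loading, spectrum offsets) remain, so bridging
    must remove them exactly."""
    config = CohortConfig(
        n_tumors=20,
        n_plexes=6,
        n_proteins=400,
        n_genes=400,
        program_size=40,
        sample_sd=0.0,
        noise_sd=0.0,
        missing_rate=0.0,
        seed=19,
    )
    return generate_cohort(config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
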