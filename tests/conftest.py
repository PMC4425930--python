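"""Shared fixtures: one fully processed default study reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from wcms.evaluate import run_synthetic_to_matrix


@pytest.fixture(scope="session")
def study():
    """A default 8-donor synthetic study processed to the feature matrix.

    Returns (truth, peaklists, matrix); expensive, so session-scoped and
    shared by every test that only needs a realistic processed experiment.
    """
    return run_synthetic_to_matrix(seed=7)


@pytest.fixture(scope="session")
def clean_study():
    """A noise-free, warp-free, variability-free study (exact arithmetic)."""
    overrides = dict(
        n_donors=2,
        noise_sigma_rel=0.0,
        warp_amplitude=0.0,
        population_effect_sd=0.0,
        donor_sd=0.0,
        donor_peak_sd=0.0,
        replicate_sd=0.0,
        peak_jitter_sd=0.0,
    )
    return run_synthetic_to_matrix(seed=5, design_overrides=overrides)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
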