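"""Shared fixtures.

The expensive regression fixtures are session-scoped and shared between the
unit and acceptance tests so that each global fit is run exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest

import hcshkin as hk


@pytest.fixture(scope="session")
def true_params() -> hk.ParameterVector:
    """Mechanism-d reference parameter set (the generating truth)."""
    return hk.default_true_parameters()


@pytest.fixture(scope="session")
def suite() -> list[hk.TestSpec]:
    return hk.default_experiment_suite()


@pytest.fixture(scope="session")
def noiseless_data(true_params, suite) -> hk.KineticDataset:
    return hk.generate_dataset(
        "d", true_params, suite, hk.NoiseModel(sigma=0.0)
    )


@pytest.fixture(scope="session")
def noisy_data(true_params, suite) -> hk.KineticDataset:
    """Synthetic stand-in campaign with GC-scale noise (sigma = 0.005)."""
    return hk.generate_dataset(
        "d", true_params, suite, hk.NoiseModel(sigma=0.005), seed=1
    )


@pytest.fixture(scope="session")
def fit_d_truth_start(noiseless_data, true_params) -> hk.FitResult:
    """Noiseless refit started at the generating parameters."""
    return hk.fit(
        "d",
        noiseless_data,
        hk.FitOptions(n_multistart=0, initial_guesses=(true_params,)),
    )


@pytest.fixture(scope="session")
def fit_d_multistart_noiseless(noiseless_data) -> hk.FitResult:
    """Noiseless refit from 20 random starts (no warm start)."""
    return hk.fit("d", noiseless_data, hk.FitOptions(n_multistart=20, seed=42))


@pytest.fixture(scope="session")
def fit_d_noisy(noisy_data) -> hk.FitResult:
    return hk.fit("d", noisy_data, hk.FitOptions(n_multistart=20, seed=42))


@pytest.fixture(scope="session")
def fit_c_noisy(noisy_data) -> hk.FitResult:
    return hk.fit("c", noisy_data, hk.FitOptions(n_multistart=8, seed=42))


@pytest.fixture(scope="session")
def fit_a_noisy(noisy_data) -> hk.FitResult:
    return hk.fit("a", noisy_data, hk.FitOptions(n_multistart=4, seed=42))


@pytest.fixture(scope="session")
def fit_b_noisy(noisy_data) -> hk.FitResult:
    return hk.fit("b", noisy_data, hk.FitOptions(n_multistart=4, seed=42))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
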