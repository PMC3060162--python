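"""Shared fixtures: solved communities reused across the suite.

The expensive solves (15-species fixpoint + deep-truncation Jacobian) are
session-scoped; everything downstream (linear theory, simulations,
statistics) reuses them.
"""

import numpy as np
import pytest

from patchcomm import (
    NoiseModel,
    geometric_mu_grid,
    linear_model,
    solve_efficiencies,
)


@pytest.fixture(scope="session")
def fp3():
    """3-species trade-off community (fast mixing; oracle workhorse)."""
    return solve_efficiencies(100.0 / 3, geometric_mu_grid(3), 0.001)


@pytest.fixture(scope="session")
def fp6():
    """6-species community with equal fixpoint abundances totalling 100."""
    return solve_efficiencies(100.0 / 6, geometric_mu_grid(6), 0.001)


@pytest.fixture(scope="session")
def fp10():
    return solve_efficiencies(100.0 / 10, geometric_mu_grid(10), 0.001)


@pytest.fixture(scope="session")
def fp15():
    """The canonical 15-species community (n_k = 100/15, alpha = 0.001)."""
    return solve_efficiencies(100.0 / 15, geometric_mu_grid(15), 0.001)


@pytest.fixture(scope="session")
def lm3(fp3):
    return linear_model(fp3, sigma_alpha=NoiseModel(0.001, 0.15).sigma_alpha)


@pytest.fixture(scope="session")
def lm6(fp6):
    return linear_model(fp6, sigma_alpha=NoiseModel(0.001, 0.045).sigma_alpha)


@pytest.fixture(scope="session")
def lm15(fp15):
    return linear_model(fp15, sigma_alpha=NoiseModel(0.001, 0.15).sigma_alpha)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
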