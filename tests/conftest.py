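"""Shared fixtures: study-scale surrogate correlation matrix and small designs."""

from __future__ import annotations

import numpy as np
import pytest

from exposobench import corrstruct, exposim


@pytest.fixture(scope="session")
def sigma237() -> corrstruct.CorrelationMatrix:
    """Study-scale (p = 237) surrogate exposure correlation matrix."""
    return corrstruct.surrogate_sigma(237, (0.83, 0.78), seed=1)


@pytest.fixture(scope="session")
def sigma50() -> corrstruct.CorrelationMatrix:
    """Reduced (p = 50) surrogate matrix for fast multivariate-method tests."""
    return corrstruct.surrogate_sigma(50, (0.83, 0.78), seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20160524)


def make_orthogonal_design(n: int, p: int, seed: int = 0) -> np.ndarray:
    """Columns orthogonal with zero mean and unit variance (Q-based)."""
    g = np.random.default_rng(seed)
    M = np.hstack([np.ones((n, 1)), g.standard_normal((n, p))])
    Q, _ = np.linalg.qr(M)
    # columns after the first are orthonormal and orthogonal to the constant,
    # hence exactly mean-zero; rescale to unit variance
    return Q[:, 1:] * np.sqrt(n)


@pytest.fixture()
def orthogonal_design():
    return make_orthogonal_design


@pytest.fixture(scope="session")
def study_dataset(sigma237) -> exposim.SimulatedDataset:
    """One baseline-scenario dataset at full study scale (k = 5)."""
    spec = exposim.scenario(1, 5)
    return exposim.simulate_run(spec, sigma237, seed=11)
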