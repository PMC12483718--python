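"""Shared fixtures: small synthetic problems and pre-fitted models."""

import numpy as np
import pytest

import facscore as fs


def make_valid_scores(n: int, r: int, p: int, seed: int = 0) -> fs.ScoreSet:
    """An exactly constraint-satisfying random score set."""
    return fs.generate_true_scores(n, r, p, seed)


def random_params(p: int, r: int, q: int | None = None,
                  seed: int = 0) -> fs.FactorParams:
    rng = np.random.default_rng(seed)
    return fs.FactorParams(
        A=rng.normal(size=(p, r)),
        psi=rng.uniform(0.2, 1.0, size=p),
        B=None if q is None else rng.normal(size=(q, r)))


@pytest.fixture(scope="session")
def small_data():
    """n=60, p=6, q=2, r=2 noisy dataset with truth."""
    data, truth = fs.generate_dataset(
        fs.SimulationDesign(n=60, p=6, q=2, r=2, rho=0.9, seed=11))
    return data, truth


@pytest.fixture(scope="session")
def small_rfe_fit(small_data):
    data, _ = small_data
    fit = fs.fit_rfe(data, 2, fs.AlgoConfig(alpha=0.01, n_starts=5, seed=3))
    return data, fit


@pytest.fixture(scope="session")
def noise_free_data():
    """rho=1 dataset: the model holds exactly."""
    data, truth = fs.generate_dataset(
        fs.SimulationDesign(n=80, p=6, q=3, r=2, rho=1.0, seed=5))
    return data, truth


@pytest.fixture(scope="session")
def demo_cluster_fits():
    """CFE and CCFE fitted to the same no-cluster demonstration data."""
    data, true_scores = fs.generate_nocluster_demo(n=200, seed=1)
    cfg = fs.AlgoConfig(alpha=0.01, n_starts=10, seed=10)
    cfe_fit, cfe_model = fs.fit_cfe(data, 2, 3, cfg)
    ccfe_fit, ccfe_model = fs.fit_ccfe(data, 2, 3, cfg)
    return data, true_scores, (cfe_fit, cfe_model), (ccfe_fit, ccfe_model)
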