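"""Entropy, KL and Kendall-tau estimators against closed-form oracles."""

import itertools

import numpy as np
import pytest

from vineflow.information import (
    InsufficientSampleError,
    UndefinedTauError,
    copula_entropy_mc,
    kendall_tau_empirical,
    kl_knn,
)
from vineflow.parametric import ParametricCopulaSpec, copula_pdf, copula_sample


class _ExactCopula:
    """Adapter exposing a parametric copula as a sample/log-density model."""

    def __init__(self, spec):
        self.spec = spec

    def sample(self, n, seed=None):
        return copula_sample(self.spec, n, seed=seed)

    def log_density(self, u):
        u = np.atleast_2d(u)
        return np.log(copula_pdf(self.spec, u[:, 0], u[:, 1]))


@pytest.mark.parametrize(
    "rho,expected,tol",
    [(0.8, 0.5 * np.log2(1 - 0.64), 0.03), (0.4, 0.5 * np.log2(1 - 0.16), 0.02)],
)
def test_entropy_mc_gaussian_closed_form(rho, expected, tol):
    """MC copula entropy of the exact Gaussian copula is (1/2) log2(1 - rho^2)."""
    est = copula_entropy_mc(_ExactCopula(ParametricCopulaSpec("gaussian", rho=rho)), K=8000, seed=1)
    assert est.value == pytest.approx(expected, abs=tol)
    assert est.std_error > 0 and est.K == 8000


def test_entropy_mc_independence_is_zero():
    est = copula_entropy_mc(_ExactCopula(ParametricCopulaSpec("independence")), K=2000, seed=2)
    assert abs(est.value) <= max(3 * est.std_error, 1e-12)


def test_entropy_requires_enough_samples(fitted_six):
    _, res = fitted_six["gaussian-weak"]
    with pytest.raises(ValueError):
        copula_entropy_mc(res.flow, K=50)


def test_entropy_mc_agrees_with_quadrature(fitted_six):
    """MC entropy of a fitted flow matches grid quadrature of -c log2 c."""
    _, res = fitted_six["clayton-weak"]
    est = copula_entropy_mc(res.flow, K=8000, seed=3)
    g = np.linspace(1e-4, 1 - 1e-4, 200)
    uu, vv = np.meshgrid(g, g)
    logc = res.log_density(np.column_stack([uu.ravel(), vv.ravel()])).reshape(200, 200)
    c = np.exp(logc)
    quad = -np.trapezoid(np.trapezoid(c * logc / np.log(2), g, axis=1), g)
    assert est.value == pytest.approx(quad, abs=3 * est.std_error + 0.02)


def test_kl_same_distribution_near_zero():
    spec = ParametricCopulaSpec("clayton", theta=2.0)
    X = copula_sample(spec, 8000, seed=4)
    Y = copula_sample(spec, 8000, seed=5)
    assert abs(kl_knn(X, Y, k=5).value) < 0.05


def test_kl_gaussian_shift_oracle():
    """1-D N(0,1) vs N(1,1): KL = 1/2 nats."""
    rng = np.random.default_rng(6)
    X = rng.normal(0, 1, (8000, 1))
    Y = rng.normal(1, 1, (8000, 1))
    assert kl_knn(X, Y, k=5).value == pytest.approx(0.5, abs=0.07)


def test_kl_correlated_gaussian_oracle():
    """2-D rho=0.8 normal vs standard normal: KL = -0.5 ln(1-rho^2),
    since trace and dimension terms cancel in this direction."""
    rng = np.random.default_rng(7)
    X = rng.multivariate_normal([0, 0], [[1, 0.8], [0.8, 1]], 8000)
    Y = rng.multivariate_normal([0, 0], np.eye(2), 8000)
    assert kl_knn(X, Y, k=5).value == pytest.approx(-0.5 * np.log(1 - 0.64), abs=0.08)


def test_kl_mean_over_replicates_near_zero():
    """Same-distribution KL is approximately unbiased around zero."""
    rng = np.random.default_rng(8)
    vals = []
    for _ in range(20):
        X = rng.uniform(0, 1, (8000, 2))
        Y = rng.uniform(0, 1, (8000, 2))
        vals.append(kl_knn(X, Y, k=5).value)
    assert -0.03 <= np.mean(vals) <= 0.05


def test_kl_k_sensitivity_runs():
    rng = np.random.default_rng(9)
    X, Y = rng.normal(size=(2, 500, 2))
    for k in (1, 5, 10):
        est = kl_knn(X, Y, k=k)
        assert est.k == k


def test_kl_insufficient_samples():
    with pytest.raises(InsufficientSampleError):
        kl_knn(np.zeros((4, 1)), np.zeros((4, 1)), k=5)


def _tau_b_bruteforce(x, y):
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        a, b = np.sign(x[i] - x[j]), np.sign(y[i] - y[j])
        if a == 0 and b == 0:
            continue
        if a == 0:
            tx += 1
        elif b == 0:
            ty += 1
        elif a == b:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / np.sqrt((n0 - _pairs_tied(x)) * (n0 - _pairs_tied(y)))


def _pairs_tied(v):
    _, counts = np.unique(v, return_counts=True)
    return float(sum(c * (c - 1) / 2 for c in counts))


def test_kendall_tau_examples():
    assert kendall_tau_empirical([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    assert kendall_tau_empirical([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
    assert kendall_tau_empirical([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(1.0 / 3.0)


def test_kendall_tau_b_matches_bruteforce_with_ties():
    rng = np.random.default_rng(10)
    for _ in range(10):
        x = rng.poisson(2.0, 40)
        y = np.clip(x + rng.poisson(1.0, 40) - 1, 0, None)
        assert kendall_tau_empirical(x, y) == pytest.approx(_tau_b_bruteforce(x, y), abs=1e-12)


def test_kendall_tau_constant_input():
    with pytest.raises(UndefinedTauError):
        kendall_tau_empirical([1, 1, 1], [1, 2, 3])
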