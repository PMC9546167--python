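"""Closed-form copula families: CDFs, densities, conditionals, samplers."""

import numpy as np
import pytest

from vineflow.parametric import (
    InvalidSpecError,
    ParametricCopulaSpec,
    copula_cdf,
    copula_hfunc,
    copula_hinv,
    copula_kendall_tau,
    copula_pdf,
    copula_sample,
)

ALL_SPECS = [
    ParametricCopulaSpec("independence"),
    ParametricCopulaSpec("clayton", theta=2.0),
    ParametricCopulaSpec("clayton", theta=5.0),
    ParametricCopulaSpec("frank", theta=3.0),
    ParametricCopulaSpec("frank", theta=-4.0),
    ParametricCopulaSpec("gaussian", rho=0.8),
    ParametricCopulaSpec("gaussian", rho=-0.5),
]


@pytest.mark.parametrize(
    "family,kwargs",
    [
        ("clayton", {"theta": -1.0}),
        ("clayton", {}),
        ("frank", {"theta": 0.0}),
        ("gaussian", {"rho": 1.0}),
        ("gaussian", {"theta": 2.0}),
        ("independence", {"theta": 1.0}),
        ("gumbel", {"theta": 2.0}),
    ],
)
def test_invalid_specs_rejected(family, kwargs):
    with pytest.raises(InvalidSpecError):
        ParametricCopulaSpec(family, **kwargs)


def test_spec_json_roundtrip():
    for spec in ALL_SPECS:
        assert ParametricCopulaSpec.from_json(spec.to_json()) == spec


def test_cdf_known_values():
    assert copula_cdf(ParametricCopulaSpec("independence"), 0.3, 0.6) == pytest.approx(0.18)
    # Clayton closed form (4 + 4 - 1)^(-1/2)
    assert copula_cdf(ParametricCopulaSpec("clayton", theta=2.0), 0.5, 0.5) == pytest.approx(
        7.0**-0.5, abs=1e-12
    )


@pytest.mark.parametrize("spec", ALL_SPECS, ids=str)
def test_cdf_uniform_margin_boundaries(spec):
    u = np.array([0.2, 0.7, 0.95])
    assert np.allclose(copula_cdf(spec, u, np.ones_like(u)), u, atol=1e-6)
    assert np.allclose(copula_cdf(spec, np.ones_like(u), u), u, atol=1e-6)
    assert np.allclose(copula_cdf(spec, u, np.zeros_like(u)), 0.0, atol=1e-9)


@pytest.mark.parametrize("spec", ALL_SPECS, ids=str)
def test_cdf_two_increasing(spec):
    rng = np.random.default_rng(3)
    u1, v1 = rng.uniform(0, 1, (2, 200))
    u2 = u1 + rng.uniform(0, 1 - u1)
    v2 = v1 + rng.uniform(0, 1 - v1)
    vol = (
        copula_cdf(spec, u2, v2)
        - copula_cdf(spec, u1, v2)
        - copula_cdf(spec, u2, v1)
        + copula_cdf(spec, u1, v1)
    )
    assert np.all(vol >= -1e-9)


def test_pdf_known_values():
    assert copula_pdf(ParametricCopulaSpec("independence"), 0.37, 0.11) == pytest.approx(1.0)
    # Gaussian copula density at the median point is (1 - rho^2)^(-1/2)
    assert copula_pdf(ParametricCopulaSpec("gaussian", rho=0.8), 0.5, 0.5) == pytest.approx(
        1.0 / np.sqrt(1 - 0.64), rel=1e-9
    )


@pytest.mark.parametrize(
    "spec",
    [
        ParametricCopulaSpec("clayton", theta=2.0),
        ParametricCopulaSpec("frank", theta=3.0),
        ParametricCopulaSpec("gaussian", rho=0.8),
    ],
    ids=str,
)
def test_pdf_matches_mixed_finite_difference_of_cdf(spec):
    """The density equals the mixed second partial of the CDF (numeric oracle)."""
    g = np.linspace(0.08, 0.92, 50)
    uu, vv = np.meshgrid(g, g)
    h = 1e-4
    num = (
        copula_cdf(spec, uu + h, vv + h)
        - copula_cdf(spec, uu - h, vv + h)
        - copula_cdf(spec, uu + h, vv - h)
        + copula_cdf(spec, uu - h, vv - h)
    ) / (4 * h * h)
    assert np.abs(copula_pdf(spec, uu, vv) - num).max() < 1e-3


def test_hfunc_known_values():
    u = np.array([0.1, 0.4, 0.9])
    assert np.allclose(copula_hfunc(ParametricCopulaSpec("independence"), u, 0.5), u)
    assert copula_hfunc(ParametricCopulaSpec("clayton", theta=2.0), 0.5, 0.5) == pytest.approx(
        8.0 * 7.0**-1.5, abs=1e-12
    )


@pytest.mark.parametrize("spec", ALL_SPECS, ids=str)
def test_hfunc_matches_cdf_derivative(spec):
    rng = np.random.default_rng(5)
    u, v = rng.uniform(0.05, 0.95, (2, 100))
    h = 1e-5
    num = (copula_cdf(spec, u, v + h) - copula_cdf(spec, u, v - h)) / (2 * h)
    assert np.abs(copula_hfunc(spec, u, v) - num).max() < 1e-4


@pytest.mark.parametrize("spec", ALL_SPECS, ids=str)
def test_hfunc_boundaries_and_monotonicity(spec):
    v = 0.37
    u = np.linspace(0, 1, 101)
    h = copula_hfunc(spec, u, v)
    assert h[0] == pytest.approx(0.0, abs=1e-9)
    assert h[-1] == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(h) >= -1e-12)


@pytest.mark.parametrize("spec", ALL_SPECS, ids=str)
def test_hinv_roundtrip(spec):
    rng = np.random.default_rng(7)
    p, v = rng.uniform(0.01, 0.99, (2, 100))
    u = copula_hinv(spec, p, v)
    assert np.abs(copula_hfunc(spec, u, v) - p).max() < 1e-8
    # p -> 0 sends u -> 0 (Clayton approaches as p^(1/(theta+1)), hence slowly)
    assert copula_hinv(spec, 1e-11, 0.5) < 0.05


def test_hinv_independence_is_identity():
    assert copula_hinv(ParametricCopulaSpec("independence"), 0.4, 0.77) == pytest.approx(0.4)


@pytest.mark.parametrize(
    "spec,tau",
    [
        (ParametricCopulaSpec("independence"), 0.0),
        (ParametricCopulaSpec("clayton", theta=5.0), 5.0 / 7.0),
        (ParametricCopulaSpec("gaussian", rho=0.8), 2.0 / np.pi * np.arcsin(0.8)),
    ],
    ids=("independence", "clayton5", "gaussian08"),
)
def test_sample_reproduces_kendall_tau(spec, tau):
    from scipy.stats import kendalltau

    u = copula_sample(spec, 8000, seed=11)
    assert u.shape == (8000, 2)
    assert kendalltau(u[:, 0], u[:, 1]).statistic == pytest.approx(tau, abs=0.03)


def test_sample_is_seeded():
    spec = ParametricCopulaSpec("frank", theta=3.0)
    assert np.array_equal(copula_sample(spec, 100, seed=1), copula_sample(spec, 100, seed=1))
    assert not np.array_equal(copula_sample(spec, 100, seed=1), copula_sample(spec, 100, seed=2))


def test_kendall_tau_closed_forms():
    assert copula_kendall_tau(ParametricCopulaSpec("clayton", theta=2.0)) == pytest.approx(0.5)
    assert copula_kendall_tau(ParametricCopulaSpec("independence")) == 0.0
    # Frank via the Debye integral
    assert copula_kendall_tau(ParametricCopulaSpec("frank", theta=3.0)) == pytest.approx(
        0.30725, abs=1e-4
    )


@pytest.mark.parametrize(
    "spec",
    [ParametricCopulaSpec("frank", theta=1e-4), ParametricCopulaSpec("gaussian", rho=1e-4)],
    ids=("frank_small", "gaussian_small"),
)
def test_weak_limits_reduce_to_independence(spec):
    g = np.linspace(0.05, 0.95, 19)
    uu, vv = np.meshgrid(g, g)
    assert np.abs(copula_cdf(spec, uu, vv) - uu * vv).max() < 1e-3
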