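"""C-vine construction: ordering, h-functions, density, sampling."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from vineflow import FlowHyper, build_flow, kendall_tau_empirical
from vineflow.cvine import (
    CVineCopula,
    CVineResults,
    VineFitConfig,
    order_variables,
    vine_hfunc,
    vine_hinv,
)
from vineflow.flows import TrainConfig
from vineflow.parametric import ParametricCopulaSpec, copula_sample
from vineflow.simulation import BenchmarkCase, build_ground_truth_vine, generate_dataset

FAST = TrainConfig(batch_size=512, max_epochs=60, lr=3e-3, patience=10, decay_stages=1)
TINY = TrainConfig(batch_size=256, max_epochs=10, lr=3e-3, patience=4, decay_stages=1)
TINY_SPACE = {"n_layers": [1], "hidden_units": [8], "n_bins": [4]}


def test_order_variables_most_connected_first(rng):
    x = rng.uniform(0, 1, 400)
    u = np.column_stack([x, np.clip(x + rng.normal(0, 0.05, 400), 0, 1), rng.uniform(0, 1, 400)])
    ordering = order_variables(u)
    assert ordering[2] == 2  # the independent column goes last
    assert set(ordering[:2]) == {0, 1}


def test_order_variables_d2_tiebreak(rng):
    u = rng.uniform(0, 1, (100, 2))
    assert list(order_variables(u)) == [0, 1]


def test_vine_hfunc_independence_flow(rng):
    flow = build_flow(FlowHyper(n_layers=2, hidden_units=8, n_bins=8, dim=2), seed=0)
    u = rng.uniform(0.05, 0.95, 50)
    v = rng.uniform(0.1, 0.9, 50)
    assert np.abs(vine_hfunc(flow, u, v) - u).max() < 0.02
    assert vine_hfunc(flow, np.ones(3), v[:3]) == pytest.approx(1.0)


def test_vine_hfunc_matches_closed_form(fitted_six):
    """Numeric h of the fitted Clayton(theta=2) flow vs the analytic value."""
    _, res = fitted_six["clayton-weak"]
    h = vine_hfunc(res.flow, np.array([0.5]), np.array([0.5]))[0]
    assert h == pytest.approx(8.0 * 7.0**-1.5, abs=0.05)


def test_vine_hinv_roundtrip(fitted_six, rng):
    _, res = fitted_six["gaussian-strong"]
    p = rng.uniform(0.02, 0.98, 200)
    v = rng.uniform(0.05, 0.95, 200)
    u = vine_hinv(res.flow, p, v)
    assert np.abs(vine_hfunc(res.flow, u, v) - p).max() < 0.01


@pytest.fixture(scope="module")
def clayton_vine():
    """4-D Clayton(theta=2) C-vine fitted with the generating ordering."""
    gt = build_ground_truth_vine(BenchmarkCase(4, "clayton", "weak", "continuous"))
    data = generate_dataset(gt, 5000, seed=31)
    cfg = VineFitConfig(
        n_trials=1, margin_method="empirical", ordering=[0, 1, 2, 3], train_cfg=FAST
    )
    return CVineCopula(data, column_types=["continuous"] * 4).fit(fit_cfg=cfg, seed=32)


def test_vine_structure_counts(clayton_vine):
    assert clayton_vine.n_pair_copulas == 6
    assert [len(t) for t in clayton_vine.pair_copulas] == [3, 2, 1]


def test_vine_tree1_recovers_tau(clayton_vine):
    for flow in clayton_vine.pair_copulas[0]:
        d = flow.sample(8000, seed=33)
        assert kendall_tau_empirical(d[:, 0], d[:, 1]) == pytest.approx(0.5, abs=0.05)


def test_vine_copula_samples_uniform_margins(clayton_vine):
    """KS uniformity at alpha=0.01, Bonferroni over the four coordinates."""
    u = clayton_vine.sample_copula(4000, seed=34)
    crit = np.sqrt(np.log(2.0 / (0.01 / 4)) / (2 * 4000))
    for i in range(4):
        assert stats.kstest(u[:, i], "uniform").statistic < crit


def test_vine_sample_reproduces_tree1_tau(clayton_vine):
    u = clayton_vine.sample_copula(6000, seed=35)
    root = clayton_vine.ordering[0]
    taus = [
        kendall_tau_empirical(u[:, root], u[:, clayton_vine.ordering[i]]) for i in (1, 2, 3)
    ]
    assert np.abs(np.array(taus) - 0.5).max() < 0.07


def test_structural_counts_d8(rng):
    data = rng.uniform(0, 1, (300, 8))
    cfg = VineFitConfig(
        n_trials=1, margin_method="empirical", train_cfg=TINY, search_space=TINY_SPACE
    )
    res = CVineCopula(data, column_types=["continuous"] * 8).fit(fit_cfg=cfg, seed=36)
    assert res.n_pair_copulas == 28


def test_independence_vine_entropies_near_zero(rng):
    from vineflow.information import copula_entropy_mc

    data = rng.uniform(0, 1, (2000, 4))
    cfg = VineFitConfig(n_trials=1, margin_method="empirical", train_cfg=FAST)
    res = CVineCopula(data, column_types=["continuous"] * 4).fit(fit_cfg=cfg, seed=37)
    for tree in res.pair_copulas:
        for flow in tree:
            est = copula_entropy_mc(flow, K=2000, seed=38)
            assert abs(est.value) < 0.1


def test_discrete_vine_sample_stays_on_support(rng):
    x = rng.poisson(5.0, (1500, 2)).astype(float)
    x[:, 1] = np.clip(x[:, 0] + rng.poisson(2.0, 1500) - 2, 0, None)
    cfg = VineFitConfig(n_trials=1, train_cfg=FAST)
    res = CVineCopula(x, column_types=["discrete", "discrete"]).fit(fit_cfg=cfg, seed=39)
    draws = res.sample(2000, seed=40)
    for i in range(2):
        assert set(np.unique(draws[:, i])) <= set(np.unique(x[:, i]))


class _SwappedFlow:
    """Duck-typed copula whose arguments are transposed."""

    def __init__(self, flow):
        self._flow = flow

    def log_density_unit(self, pts):
        return self._flow.log_density_unit(np.asarray(pts)[:, ::-1])


def test_d2_log_density_invariant_to_ordering(rng):
    """At d=2 relabelling the root just transposes the single copula."""
    spec = ParametricCopulaSpec("gaussian", rho=0.7)
    u = copula_sample(spec, 1200, seed=41)
    x = stats.norm.ppf(u)
    cfg = VineFitConfig(n_trials=1, ordering=[0, 1], train_cfg=FAST)
    res = CVineCopula(x).fit(fit_cfg=cfg, seed=42)
    res_swapped = dataclasses.replace(
        res,
        ordering=np.array([1, 0]),
        pair_copulas=[[_SwappedFlow(res.pair_copulas[0][0])]],
    )
    pts = x[:100]
    assert np.allclose(res.logpdf(pts), res_swapped.logpdf(pts), atol=1e-9)


def test_logpdf_matches_ground_truth_entropy():
    """Held-out average negative log-density approximates the true joint
    differential entropy (Monte-Carlo oracle from the parametric sampler)."""
    spec = ParametricCopulaSpec("gaussian", rho=0.8)
    u = copula_sample(spec, 5000, seed=43)
    x = stats.norm.ppf(u)
    res = CVineCopula(x).fit(fit_cfg=VineFitConfig(n_trials=1), seed=44)
    u_test = copula_sample(spec, 3000, seed=45)
    x_test = stats.norm.ppf(u_test)
    nll = -res.logpdf(x_test).mean()
    # bivariate normal entropy: ln(2 pi e) + 0.5 ln(1 - rho^2)
    h_true = np.log(2 * np.pi * np.e) + 0.5 * np.log(1 - 0.64)
    assert nll == pytest.approx(h_true, abs=0.1)


def test_bad_ordering_rejected(rng):
    data = rng.uniform(0, 1, (200, 3))
    with pytest.raises(ValueError):
        CVineCopula(data).fit(fit_cfg=VineFitConfig(ordering=[0, 1, 1]), seed=0)


def test_vine_save_load_roundtrip(tmp_path, clayton_vine):
    clayton_vine.save(tmp_path / "vine")
    reloaded = CVineResults.load(tmp_path / "vine")
    a = clayton_vine.sample_copula(100, seed=46)
    b = reloaded.sample_copula(100, seed=46)
    assert np.allclose(a, b)
    assert "tree" in reloaded.summary()
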