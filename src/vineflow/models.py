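"""Model/Results wrappers around the spline-flow machinery.

`MarginFlow` models a single variable's distribution; `PairCopulaFlow`
models a bivariate copula density from pseudo-observations on the unit
square.  Both follow the familiar pattern: construct from data, call
``fit()``, get a results object carrying the trained flow, diagnostics and
``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .flows import (
    FlowHyper,
    FlowNetwork,
    TrainConfig,
    build_flow,
    fit_flow,
    load_flow,
    random_search,
    save_flow,
)
from .information import EntropyEstimate, copula_entropy_mc

__all__ = ["MarginFlow", "MarginFlowResults", "PairCopulaFlow", "PairCopulaFlowResults"]


def _summary_lines(title: str, rows: list) -> str:
    width = max(len(k) for k, _ in rows) + 2
    lines = [title, "=" * len(title)]
    lines += [f"{k:<{width}}{v}" for k, v in rows]
    return "\n".join(lines)


class MarginFlow:
    """Univariate density model: a 1-D spline flow on an affine rescaling
    of the data range (padded by three sample standard deviations so the
    learned density has support beyond the observed extremes)."""

    def __init__(self, data):
        data = np.asarray(data, dtype=float).ravel()
        if len(data) < 100:
            raise ValueError("need at least 100 observations")
        if np.all(data == data[0]):
            raise ValueError("constant data has a degenerate margin")
        self.data = data
        sd = data.std(ddof=1)
        lo = data.min() - 3.0 * sd
        hi = data.max() + 3.0 * sd
        self.scaling = (lo, hi - lo)

    def fit(
        self,
        hyper: Optional[FlowHyper] = None,
        train_cfg: Optional[TrainConfig] = None,
        seed: int = 0,
    ) -> "MarginFlowResults":
        hyper = hyper or FlowHyper(n_layers=2, hidden_units=1, n_bins=16, dim=1)
        shift, scale = self.scaling
        z = (self.data - shift) / scale
        flow = build_flow(hyper, seed=seed)
        fit_flow(flow, z[:, None], train_cfg=train_cfg, seed=seed)
        flow.scaling = (np.float64(shift), np.float64(scale))
        return MarginFlowResults(flow=flow, nobs=len(self.data))


@dataclass
class MarginFlowResults:
    flow: FlowNetwork
    nobs: int

    @property
    def discrete(self) -> bool:
        return False

    def logpdf(self, x) -> np.ndarray:
        return self.flow.log_density(np.asarray(x, dtype=float))

    def sample(self, n: int, seed=None) -> np.ndarray:
        return self.flow.sample(n, seed=seed)[:, 0]

    def cdf(self, x) -> np.ndarray:
        """The flow's forward transform is monotone, hence its CDF estimate."""
        shift, scale = self.flow.scaling
        z = np.clip((np.asarray(x, dtype=float) - shift) / scale, 0.0, 1.0)
        u, _, _ = self.flow._forward(z[:, None])
        return u[:, 0]

    def quantile(self, q) -> np.ndarray:
        q = np.atleast_1d(np.asarray(q, dtype=float))
        x = self.flow._inverse(q[:, None])[:, 0]
        shift, scale = self.flow.scaling
        return x * scale + shift

    def summary(self) -> str:
        h = self.flow.hyper
        return _summary_lines(
            "MarginFlow results",
            [
                ("nobs", self.nobs),
                ("layers", h.n_layers),
                ("spline bins", h.n_bins),
                ("epochs run", len(self.flow.train_log)),
                ("val loglik", round(self.flow.best_val_loglik, 4)),
            ],
        )

    def save(self, path) -> None:
        save_flow(self.flow, path)

    @classmethod
    def load(cls, path) -> "MarginFlowResults":
        return cls(flow=load_flow(path), nobs=0)


class PairCopulaFlow:
    """Bivariate copula model fitted to pseudo-observations in (0,1)^2.

    ``fit`` with an explicit ``hyper`` trains that architecture; with
    ``n_trials > 1`` it runs a random hyperparameter search and keeps the
    configuration with the best validation log-likelihood.
    """

    def __init__(self, u: np.ndarray):
        u = np.asarray(u, dtype=float)
        if u.ndim != 2 or u.shape[1] != 2:
            raise ValueError("expected an (n, 2) array of pseudo-observations")
        if np.any((u <= 0) | (u >= 1)):
            raise ValueError("pseudo-observations must lie strictly inside (0,1)^2")
        self.u = u

    def fit(
        self,
        hyper: Optional[FlowHyper] = None,
        train_cfg: Optional[TrainConfig] = None,
        n_trials: int = 1,
        search_space: Optional[dict] = None,
        seed: int = 0,
    ) -> "PairCopulaFlowResults":
        if n_trials > 1 or search_space is not None:
            flow = random_search(
                self.u, dim=2, search_space=search_space, n_trials=n_trials,
                seed=seed, train_cfg=train_cfg,
            )
        else:
            flow = build_flow(hyper or FlowHyper(dim=2), seed=seed)
            fit_flow(flow, self.u, train_cfg=train_cfg, seed=seed)
        if flow.calibration is None:
            flow.calibrate_margins()
        return PairCopulaFlowResults(flow=flow, nobs=len(self.u))


@dataclass
class PairCopulaFlowResults:
    flow: FlowNetwork
    nobs: int

    def log_density(self, u) -> np.ndarray:
        return self.flow.log_density(u)

    logpdf = log_density

    def sample(self, n: int, seed=None) -> np.ndarray:
        return self.flow.sample(n, seed=seed)

    def entropy(self, K: int = 8000, seed=None) -> EntropyEstimate:
        """Monte-Carlo copula entropy in bits; its negative estimates MI."""
        return copula_entropy_mc(self.flow, K=K, seed=seed)

    def plot_density(self, ax=None, grid: int = 100, n_scatter: int = 0, seed=None):
        """Heatmap of the fitted copula density, optionally with model draws."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        g = np.linspace(1e-3, 1 - 1e-3, grid)
        uu, vv = np.meshgrid(g, g)
        dens = np.exp(self.log_density(np.column_stack([uu.ravel(), vv.ravel()])))
        ax.pcolormesh(g, g, dens.reshape(grid, grid), shading="auto")
        if n_scatter:
            d = self.sample(n_scatter, seed=seed)
            ax.plot(d[:, 0], d[:, 1], ".", ms=2, color="w", alpha=0.5)
        ax.set_xlabel("u")
        ax.set_ylabel("v")
        return ax

    def summary(self) -> str:
        h = self.flow.hyper
        ent = self.entropy(K=2000, seed=0)
        return _summary_lines(
            "PairCopulaFlow results",
            [
                ("nobs", self.nobs),
                ("layers", h.n_layers),
                ("hidden units", h.hidden_units),
                ("spline bins", h.n_bins),
                ("epochs run", len(self.flow.train_log)),
                ("val loglik", round(self.flow.best_val_loglik, 4)),
                ("copula entropy (bits)", f"{ent.value:.3f} +- {ent.std_error:.3f}"),
            ],
        )

    def save(self, path) -> None:
        save_flow(self.flow, path)

    @classmethod
    def load(cls, path) -> "PairCopulaFlowResults":
        return cls(flow=load_flow(path), nobs=0)
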