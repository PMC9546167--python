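"""Canonical vine (C-vine) copulas with spline-flow pair copulas.

The joint density of d variables factorizes into d margins and d(d-1)/2
bivariate conditional copulas arranged in trees: tree 1 links a root
variable to all others, tree 2 links a second root to the rest conditionally
on the first, and so on.  Conditional pseudo-observations are propagated
between trees with h-functions h(u|v) = dC(u,v)/dv, computed here by
numerical integration of the fitted flow densities, and sampling inverts the
same recursion (inverse Rosenblatt).  The simplifying assumption is
hard-wired: deeper-tree copulas depend on the conditioning variables only
through the conditional CDFs.

Fitting follows Inference-for-Margins: margins first, then pair copulas
tree by tree, each chosen by random hyperparameter search on a validation
split.  Discrete (count) variables enter copula space through the seeded
distributional transform and leave it by quantile lookup in their empirical
pmf, so sampled counts always land on the observed support.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .flows import FlowNetwork, TrainConfig, load_flow, random_search, save_flow
from .information import kendall_tau_empirical
from .models import MarginFlow, MarginFlowResults
from .transforms import (
    CLAMP_EPS,
    ContinuousECDF,
    DiscreteMarginTable,
    distributional_transform,
    fit_empirical_margin,
    infer_discrete,
)

__all__ = [
    "CVineCopula",
    "CVineResults",
    "VineFitConfig",
    "order_variables",
    "vine_hfunc",
    "vine_hinv",
    "load_vine",
]

_H_GRID = np.linspace(CLAMP_EPS, 1.0 - CLAMP_EPS, 256)

# compact default search space for pair copulas inside a vine; the full
# space of flows.DEFAULT_SEARCH_SPACE can be requested via VineFitConfig
_VINE_SEARCH_SPACE = {"n_layers": [1, 2], "hidden_units": [16, 32], "n_bins": [8, 16]}

# single-stage schedule for the many pair copulas inside a vine; standalone
# PairCopulaFlow fits default to the longer two-stage TrainConfig schedule
VINE_TRAIN_CFG = TrainConfig(
    batch_size=512, max_epochs=150, lr=3e-3, patience=15, decay_stages=1
)


class VineFitError(RuntimeError):
    pass


def order_variables(u: np.ndarray) -> np.ndarray:
    """C-vine variable ordering: decreasing sum of absolute Kendall's tau.

    The most rank-connected variable roots tree 1; ties break on the
    original column index.  Absolute values are used so strong negative
    dependence counts as connectivity.
    """
    u = np.asarray(u, dtype=float)
    n, d = u.shape
    if n < 10 or d < 2:
        raise ValueError("need at least 10 observations of at least 2 variables")
    scores = np.zeros(d)
    for i in range(d):
        for j in range(i + 1, d):
            t = abs(kendall_tau_empirical(u[:, i], u[:, j]))
            scores[i] += t
            scores[j] += t
    return np.lexsort((np.arange(d), -scores))


def _conditional_cdf_grid(flow: FlowNetwork, v: np.ndarray, chunk: int = 512) -> np.ndarray:
    """Normalized conditional CDF of the flow's first coordinate given the
    second, evaluated on the fixed integration grid for each v."""
    v = np.asarray(v, dtype=float)
    G = len(_H_GRID)
    dx = np.diff(_H_GRID)
    out = np.empty((len(v), G))
    for s in range(0, len(v), chunk):
        vv = v[s : s + chunk]
        pts = np.empty((len(vv) * G, 2))
        pts[:, 0] = np.tile(_H_GRID, len(vv))
        pts[:, 1] = np.repeat(vv, G)
        c = np.exp(flow.log_density_unit(pts)).reshape(len(vv), G)
        cum = np.concatenate(
            [np.zeros((len(vv), 1)), np.cumsum(0.5 * (c[:, 1:] + c[:, :-1]) * dx, axis=1)],
            axis=1,
        )
        out[s : s + chunk] = cum / cum[:, -1:]
    return out


def vine_hfunc(copula_flow: FlowNetwork, u, v) -> np.ndarray:
    """h(u | v) = dC(u, v)/dv for a fitted 2-D copula flow, by numerical
    integration of the flow density over a fixed 256-point grid."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    v = np.broadcast_to(np.atleast_1d(np.asarray(v, dtype=float)), u.shape)
    cum = _conditional_cdf_grid(copula_flow, v)
    j = np.clip(np.searchsorted(_H_GRID, u), 1, len(_H_GRID) - 1)
    x0, x1 = _H_GRID[j - 1], _H_GRID[j]
    w = np.clip((u - x0) / (x1 - x0), 0.0, 1.0)
    ar = np.arange(len(u))
    h = cum[ar, j - 1] * (1 - w) + cum[ar, j] * w
    h[u >= 1.0 - CLAMP_EPS] = 1.0
    h[u <= CLAMP_EPS] = 0.0
    return h


def vine_hinv(copula_flow: FlowNetwork, p, v) -> np.ndarray:
    """Inverse h-function: u with h(u | v) = p, by monotone interpolation of
    the same gridded conditional CDF used by :func:`vine_hfunc`."""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    v = np.broadcast_to(np.atleast_1d(np.asarray(v, dtype=float)), p.shape)
    cum = _conditional_cdf_grid(copula_flow, v)
    j = np.clip((cum < p[:, None]).sum(axis=1), 1, len(_H_GRID) - 1)
    ar = np.arange(len(p))
    c0, c1 = cum[ar, j - 1], cum[ar, j]
    w = np.clip((p - c0) / np.maximum(c1 - c0, 1e-300), 0.0, 1.0)
    u = _H_GRID[j - 1] * (1 - w) + _H_GRID[j] * w
    return np.clip(u, CLAMP_EPS, 1.0 - CLAMP_EPS)


@dataclass
class VineFitConfig:
    """Settings for sequential vine fitting.

    ``n_trials``/``search_space`` control the per-copula random
    hyperparameter search; ``margin_method`` selects spline-flow margins
    ("flow", required for joint log-densities of continuous columns) or
    plain empirical margins ("empirical", faster; copula-space work only);
    ``jitter_reps`` is the number of distributional-transform replicates
    averaged when evaluating densities of discrete columns.
    """

    n_trials: int = 3
    search_space: Optional[dict] = None
    train_cfg: Optional[TrainConfig] = None
    margin_method: str = "flow"
    jitter_reps: int = 10
    ordering: Optional[Sequence[int]] = None  # override the tau-based ordering


class CVineCopula:
    """C-vine copula model for an (n, d) matrix of mixed-type observations.

    ``column_types`` may list "continuous"/"discrete" per column; by default
    a column is flagged discrete when it is integer-valued with at most
    sqrt(n) distinct values.
    """

    def __init__(self, data, column_types=None, column_names=None):
        if isinstance(data, pd.DataFrame):
            column_names = column_names or list(map(str, data.columns))
            data = data.to_numpy(dtype=float)
        data = np.asarray(data, dtype=float)
        if data.ndim != 2 or data.shape[1] < 2:
            raise ValueError("need an (n, d>=2) data matrix")
        self.data = data
        n, d = data.shape
        self.column_names = column_names or [f"x{i}" for i in range(d)]
        if column_types is None:
            self.discrete = np.array([infer_discrete(data[:, i]) for i in range(d)])
        else:
            if len(column_types) != d:
                raise ValueError("one column type per column required")
            self.discrete = np.array([t == "discrete" for t in column_types])

    def fit(self, fit_cfg: Optional[VineFitConfig] = None, seed: int = 0) -> "CVineResults":
        cfg = fit_cfg or VineFitConfig()
        X = self.data
        n, d = X.shape
        if n < 100:
            raise ValueError("need at least 100 observations")
        root = np.random.SeedSequence(seed)
        margin_seeds, dt_seed, pair_root = root.spawn(3)

        margins = []
        for i, mseed in zip(range(d), margin_seeds.spawn(d)):
            if self.discrete[i]:
                margins.append(fit_empirical_margin(X[:, i], discrete=True))
            elif cfg.margin_method == "flow":
                margins.append(
                    MarginFlow(X[:, i]).fit(
                        train_cfg=cfg.train_cfg, seed=int(mseed.generate_state(1)[0] % 2**31)
                    )
                )
            else:
                margins.append(fit_empirical_margin(X[:, i], discrete=False))

        U = _pseudo_observations(X, self.discrete, margins, seed=dt_seed)
        if cfg.ordering is not None:
            ordering = np.asarray(cfg.ordering)
            if sorted(ordering.tolist()) != list(range(d)):
                raise ValueError("ordering must be a permutation of the columns")
        else:
            ordering = order_variables(U)
        V = U[:, ordering].copy()

        pair_copulas: List[List[FlowNetwork]] = []
        diagnostics: List[List[dict]] = []
        pair_seeds = iter(pair_root.spawn(d * (d - 1) // 2))
        for j in range(d - 1):
            tree: List[FlowNetwork] = []
            tree_diag: List[dict] = []
            rootcol = V[:, j].copy()
            for i in range(j + 1, d):
                u_pair = np.column_stack([V[:, i], rootcol])
                pseed = int(next(pair_seeds).generate_state(1)[0] % 2**31)
                try:
                    flow = random_search(
                        u_pair,
                        dim=2,
                        search_space=cfg.search_space or _VINE_SEARCH_SPACE,
                        n_trials=cfg.n_trials,
                        seed=pseed,
                        train_cfg=cfg.train_cfg or VINE_TRAIN_CFG,
                    )
                except Exception as exc:
                    raise VineFitError(f"pair copula fit failed at tree {j+1}, pair {i-j}") from exc
                tree.append(flow)
                tree_diag.append(
                    {
                        "tree": j + 1,
                        "pair": i - j,
                        "val_loglik": flow.best_val_loglik,
                        "hyper": dataclasses.asdict(flow.hyper),
                    }
                )
            if j < d - 2:
                for i in range(j + 1, d):
                    V[:, i] = vine_hfunc(tree[i - j - 1], V[:, i], rootcol)
            pair_copulas.append(tree)
            diagnostics.append(tree_diag)

        return CVineResults(
            ordering=np.asarray(ordering),
            margins=margins,
            discrete=self.discrete.copy(),
            pair_copulas=pair_copulas,
            column_names=list(self.column_names),
            fit_diagnostics=diagnostics,
            nobs=n,
            jitter_reps=cfg.jitter_reps,
        )


def _pseudo_observations(X, discrete, margins, seed) -> np.ndarray:
    """Map raw columns to (0,1): rank/(n+1) for continuous columns, the
    distributional transform for discrete ones."""
    n, d = X.shape
    U = np.empty((n, d))
    seeds = seed.spawn(d) if isinstance(seed, np.random.SeedSequence) else [None] * d
    for i in range(d):
        if discrete[i]:
            margin = margins[i]
            U[:, i] = distributional_transform(
                X[:, i].astype(np.int64), margin, seed=np.random.default_rng(seeds[i])
            )
        else:
            ecdf = ContinuousECDF(X[:, i])
            U[:, i] = ecdf.evaluate(X[:, i])
    return np.clip(U, CLAMP_EPS, 1 - CLAMP_EPS)


@dataclass
class CVineResults:
    """Fitted C-vine: ordering, margins and the triangular copula array.

    ``pair_copulas[j][i]`` is the flow of tree j+1 linking the tree's root
    to the (i+1)-th remaining variable; its first coordinate is the non-root
    variable and its second the root, so h-functions condition on the root.
    """

    ordering: np.ndarray
    margins: list
    discrete: np.ndarray
    pair_copulas: List[List[FlowNetwork]]
    column_names: list
    fit_diagnostics: list
    nobs: int
    jitter_reps: int = 10

    @property
    def dim(self) -> int:
        return len(self.ordering)

    @property
    def n_pair_copulas(self) -> int:
        return sum(len(t) for t in self.pair_copulas)

    # -- density -------------------------------------------------------------
    def _copula_logdensity_given_u(self, V: np.ndarray) -> np.ndarray:
        """Sum of pair-copula log densities for pseudo-obs already ordered."""
        V = V.copy()
        d = self.dim
        lc = np.zeros(len(V))
        for j in range(d - 1):
            rootcol = V[:, j].copy()
            for i in range(j + 1, d):
                pts = np.column_stack([V[:, i], rootcol])
                lc += self.pair_copulas[j][i - j - 1].log_density_unit(pts)
            if j < d - 2:
                for i in range(j + 1, d):
                    V[:, i] = vine_hfunc(self.pair_copulas[j][i - j - 1], V[:, i], rootcol)
        return lc

    def logpdf(self, X, seed: int = 0) -> np.ndarray:
        """Joint log-density log f(x) = sum_k log f_k(x_k) + sum log c(...).

        Discrete columns contribute their pmf to the margin term and enter
        the copula terms through the seeded distributional transform,
        averaged over ``jitter_reps`` replicates.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.dim:
            raise ValueError("dimension mismatch with fitted vine")
        logf = np.zeros(len(X))
        for i in range(self.dim):
            m = self.margins[i]
            if self.discrete[i]:
                logf += m.log_pmf(X[:, i].astype(np.int64))
            elif isinstance(m, MarginFlowResults):
                logf += m.logpdf(X[:, i])
            else:
                raise ValueError(
                    "joint density needs flow margins for continuous columns; "
                    "refit with margin_method='flow'"
                )
        R = self.jitter_reps if bool(self.discrete.any()) else 1
        root = np.random.SeedSequence(seed)
        reps = []
        for r, ss in enumerate(root.spawn(R)):
            U = np.empty_like(X)
            seeds = ss.spawn(self.dim)
            for i in range(self.dim):
                m = self.margins[i]
                if self.discrete[i]:
                    U[:, i] = distributional_transform(
                        X[:, i].astype(np.int64), m, seed=np.random.default_rng(seeds[i])
                    )
                elif isinstance(m, MarginFlowResults):
                    U[:, i] = m.cdf(X[:, i])
                else:
                    U[:, i] = m.evaluate(X[:, i])
            U = np.clip(U, CLAMP_EPS, 1 - CLAMP_EPS)
            reps.append(self._copula_logdensity_given_u(U[:, self.ordering]))
        lc = logsumexp(np.stack(reps), axis=0) - np.log(R)
        return logf + lc

    # -- sampling ------------------------------------------------------------
    def sample_copula(self, n: int, seed=None) -> np.ndarray:
        """Draw n points from the vine copula (unit hypercube, original
        column order) by inverse-Rosenblatt sampling."""
        rng = np.random.default_rng(seed)
        d = self.dim
        w = rng.uniform(CLAMP_EPS, 1 - CLAMP_EPS, size=(n, d))
        v = [[None] * d for _ in range(d)]
        u_ord = np.empty((n, d))
        v[0][0] = w[:, 0]
        u_ord[:, 0] = w[:, 0]
        for i in range(1, d):
            t = w[:, i]
            for k in range(i - 1, -1, -1):
                t = vine_hinv(self.pair_copulas[k][i - k - 1], t, v[k][k])
            u_ord[:, i] = t
            v[i][0] = t
            if i < d - 1:
                for j in range(i):
                    v[i][j + 1] = vine_hfunc(
                        self.pair_copulas[j][i - j - 1], v[i][j], v[j][j]
                    )
        u = np.empty_like(u_ord)
        u[:, self.ordering] = u_ord
        return u

    def sample(self, n: int, seed=None) -> np.ndarray:
        """Draw n joint observations: copula draws pushed through the margin
        quantile maps (counts land exactly on the observed support)."""
        u = self.sample_copula(n, seed=seed)
        X = np.empty_like(u)
        for i in range(self.dim):
            m = self.margins[i]
            X[:, i] = m.quantile(u[:, i])
        return X

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "CVineCopula results",
            "===================",
            f"variables     {self.dim} ({', '.join(self.column_names)})",
            f"nobs          {self.nobs}",
            f"ordering      {[self.column_names[i] for i in self.ordering]}",
            f"pair copulas  {self.n_pair_copulas}",
            "",
            f"{'tree':>4} {'pair':>4} {'val loglik':>11}  layers bins hidden",
        ]
        for tree in self.fit_diagnostics:
            for rec in tree:
                h = rec["hyper"]
                lines.append(
                    f"{rec['tree']:>4} {rec['pair']:>4} {rec['val_loglik']:>11.4f}"
                    f"  {h['n_layers']:>6} {h['n_bins']:>4} {h['hidden_units']:>6}"
                )
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "ordering": self.ordering.tolist(),
            "discrete": self.discrete.astype(bool).tolist(),
            "column_names": self.column_names,
            "fit_diagnostics": self.fit_diagnostics,
            "nobs": self.nobs,
            "jitter_reps": self.jitter_reps,
            "margins": [],
        }
        for i, m in enumerate(self.margins):
            if isinstance(m, DiscreteMarginTable):
                meta["margins"].append(
                    {"kind": "table", "support": m.support.tolist(), "pmf": m.pmf.tolist()}
                )
            elif isinstance(m, ContinuousECDF):
                meta["margins"].append(
                    {"kind": "ecdf", "sorted_values": m.sorted_values.tolist()}
                )
            else:
                meta["margins"].append({"kind": "flow", "nobs": m.nobs})
                m.save(path / f"margin_{i}")
        (path / "vine.json").write_text(json.dumps(meta))
        for j, tree in enumerate(self.pair_copulas):
            for i, flow in enumerate(tree):
                save_flow(flow, path / f"tree_{j+1}" / f"pair_{i+1}")

    @classmethod
    def load(cls, path) -> "CVineResults":
        path = Path(path)
        meta = json.loads((path / "vine.json").read_text())
        margins = []
        for i, m in enumerate(meta["margins"]):
            if m["kind"] == "table":
                margins.append(DiscreteMarginTable(np.asarray(m["support"]), np.asarray(m["pmf"])))
            elif m["kind"] == "ecdf":
                margins.append(ContinuousECDF(np.asarray(m["sorted_values"])))
            else:
                margins.append(MarginFlowResults(flow=load_flow(path / f"margin_{i}"), nobs=m["nobs"]))
        d = len(meta["ordering"])
        pair_copulas = []
        for j in range(d - 1):
            pair_copulas.append(
                [load_flow(path / f"tree_{j+1}" / f"pair_{i+1}") for i in range(d - j - 1)]
            )
        return cls(
            ordering=np.asarray(meta["ordering"]),
            margins=margins,
            discrete=np.asarray(meta["discrete"], dtype=bool),
            pair_copulas=pair_copulas,
            column_names=meta["column_names"],
            fit_diagnostics=meta["fit_diagnostics"],
            nobs=meta["nobs"],
            jitter_reps=meta["jitter_reps"],
        )


def load_vine(path) -> CVineResults:
    return CVineResults.load(path)
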