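"""Synthetic ground-truth vines, the simulation benchmark, and a synthetic
spike-train fixture.

The benchmark design: C-vines of dimension 4 or 8 whose pair copulas all
belong to one parametric family at one dependence strength — Clayton
(theta 2 weak / 5 strong), Frank (theta 3 / 7) or Gaussian (rho 0.4 / 0.8) —
with standard-normal (continuous) or Poisson(5) (discrete) margins.  Each
repetition draws n_train samples, fits a spline-flow C-vine, then scores
every fitted pair copula by the kNN KL divergence between n_eval of its
draws and n_eval draws of the matching parametric copula, alongside its
Monte-Carlo copula entropy.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cvine import _VINE_SEARCH_SPACE, VINE_TRAIN_CFG, VineFitConfig
from .flows import random_search
from .information import copula_entropy_mc, kl_knn
from .transforms import (
    CLAMP_EPS,
    ContinuousECDF,
    distributional_transform,
    fit_empirical_margin,
)
from .parametric import (
    ParametricCopulaSpec,
    copula_hfunc,
    copula_hinv,
    copula_sample,
)

__all__ = [
    "BenchmarkCase",
    "ParametricCVine",
    "build_ground_truth_vine",
    "generate_dataset",
    "run_benchmark",
    "aggregate_results",
    "generate_v1_like_fixture",
    "STRENGTH_PARAMS",
]

STRENGTH_PARAMS = {
    ("clayton", "weak"): {"theta": 2.0},
    ("clayton", "strong"): {"theta": 5.0},
    ("frank", "weak"): {"theta": 3.0},
    ("frank", "strong"): {"theta": 7.0},
    ("gaussian", "weak"): {"rho": 0.4},
    ("gaussian", "strong"): {"rho": 0.8},
}


@dataclass(frozen=True)
class BenchmarkCase:
    """One cell of the simulation design."""

    dim: int = 4
    family: str = "clayton"
    strength: str = "weak"
    data_type: str = "continuous"

    def __post_init__(self):
        if self.dim not in (4, 8):
            raise ValueError("dim must be 4 or 8")
        if (self.family, self.strength) not in STRENGTH_PARAMS:
            raise ValueError(f"unknown family/strength {self.family}/{self.strength}")
        if self.data_type not in ("continuous", "discrete"):
            raise ValueError("data_type must be continuous or discrete")

    @property
    def spec(self) -> ParametricCopulaSpec:
        return ParametricCopulaSpec(self.family, **STRENGTH_PARAMS[(self.family, self.strength)])

    def label(self) -> str:
        return f"{self.family}-{self.strength}-{self.dim}d-{self.data_type}"


class ParametricCVine:
    """Ground-truth C-vine: every pair copula is the same parametric copula,
    margins are standard normal or Poisson(lambda=5)."""

    def __init__(self, dim: int, spec: ParametricCopulaSpec, data_type: str = "continuous",
                 poisson_rate: float = 5.0):
        self.dim = dim
        self.spec = spec
        self.data_type = data_type
        self.poisson_rate = poisson_rate

    @property
    def n_pair_copulas(self) -> int:
        return self.dim * (self.dim - 1) // 2

    def sample_copula(self, n: int, seed=None) -> np.ndarray:
        """Inverse-Rosenblatt sampling with the family's closed-form inverse
        h-functions (the C-vine simulation recursion)."""
        rng = np.random.default_rng(seed)
        d = self.dim
        eps = 1e-12
        w = rng.uniform(eps, 1 - eps, size=(n, d))
        v = [[None] * d for _ in range(d)]
        u = np.empty((n, d))
        v[0][0] = w[:, 0]
        u[:, 0] = w[:, 0]
        for i in range(1, d):
            t = w[:, i]
            for k in range(i - 1, -1, -1):
                t = copula_hinv(self.spec, t, v[k][k])
            u[:, i] = t
            v[i][0] = t
            if i < d - 1:
                for j in range(i):
                    v[i][j + 1] = copula_hfunc(self.spec, v[i][j], v[j][j])
        return np.clip(u, eps, 1 - eps)

    def sample(self, n: int, seed=None) -> np.ndarray:
        """Copula draws pushed through the margin quantiles."""
        u = self.sample_copula(n, seed=seed)
        if self.data_type == "discrete":
            return stats.poisson(self.poisson_rate).ppf(u)
        return stats.norm.ppf(u)


def build_ground_truth_vine(case: BenchmarkCase) -> ParametricCVine:
    return ParametricCVine(case.dim, case.spec, case.data_type)


def generate_dataset(vine: ParametricCVine, n: int, seed=None) -> np.ndarray:
    if n < 1:
        raise ValueError("n must be >= 1")
    return vine.sample(n, seed=seed)


def _pseudo_obs_matrix(data: np.ndarray, data_type: str, rng) -> np.ndarray:
    """Pseudo-observations for benchmark training data: rank/(n+1) for
    continuous columns, distributional transform for counts."""
    n, d = data.shape
    U = np.empty((n, d))
    for i in range(d):
        if data_type == "discrete":
            margin = fit_empirical_margin(data[:, i], discrete=True)
            U[:, i] = distributional_transform(data[:, i].astype(np.int64), margin, seed=rng)
        else:
            U[:, i] = ContinuousECDF(data[:, i]).evaluate(data[:, i])
    return np.clip(U, CLAMP_EPS, 1 - CLAMP_EPS)


def _true_pseudo_obs(data: np.ndarray, vine: ParametricCVine, rng) -> np.ndarray:
    """Ground-truth-side pseudo-observations: the known margins' probability
    transform (normal CDF), or the exact-margin distributional transform for
    Poisson counts.

    For continuous data this recovers exact copula samples; for counts it
    yields the distributional-transform copula of the discretized joint
    distribution — the object a non-parametric estimator of count data
    actually targets.
    """
    n, d = data.shape
    U = np.empty((n, d))
    if vine.data_type == "discrete":
        pois = stats.poisson(vine.poisson_rate)
        F = pois.cdf(data)
        F_minus = pois.cdf(data - 1.0)
        V = rng.uniform(size=data.shape)
        U = F_minus + V * (F - F_minus)
    else:
        U = stats.norm.cdf(data)
    return np.clip(U, CLAMP_EPS, 1 - CLAMP_EPS)


def run_benchmark(
    cases: Sequence[BenchmarkCase],
    n_train: int = 5000,
    n_eval: int = 8000,
    reps: int = 10,
    seed: int = 0,
    fit_cfg: Optional[VineFitConfig] = None,
) -> pd.DataFrame:
    """Run the simulation study: one row per fitted pair copula per
    repetition with the kNN KL to ground-truth copula samples (nats), the
    MC copula entropy (bits, K = n_eval) and the fit time.

    The vine structure is known by construction, so the ordering is fixed to
    the generating one, and the conditional pseudo-observations that train
    the deeper-tree copulas are built with the exact parametric h-functions
    on both sides; each pair copula's score therefore isolates that copula's
    estimation quality.  Each repetition redraws both the training data and
    the fit initialization.
    """
    cfg = fit_cfg or VineFitConfig(margin_method="empirical", n_trials=2)
    rows = []
    for ci, case in enumerate(cases):
        gt = build_ground_truth_vine(case)
        d = case.dim
        case_root = np.random.SeedSequence(entropy=seed, spawn_key=(ci,))
        for rep, ss in enumerate(case_root.spawn(reps), start=1):
            s_data, s_dt, s_fit, s_eval, s_gt = ss.spawn(5)
            data = generate_dataset(gt, n_train, seed=np.random.default_rng(s_data))
            U = _pseudo_obs_matrix(data, case.data_type, np.random.default_rng(s_dt))
            gt_rng = np.random.default_rng(s_gt)
            eval_data = generate_dataset(gt, n_eval, seed=gt_rng)
            U_gt = _true_pseudo_obs(eval_data, gt, gt_rng)
            fit_seeds = iter(s_fit.spawn(gt.n_pair_copulas))
            eval_seeds = iter(s_eval.spawn(2 * gt.n_pair_copulas))
            curr = U.copy()
            curr_gt = U_gt.copy()
            for j in range(d - 1):
                rootcol = curr[:, j].copy()
                root_gt = curr_gt[:, j].copy()
                for i in range(j + 1, d):
                    u_pair = np.column_stack([curr[:, i], rootcol])
                    t0 = time.time()
                    flow = random_search(
                        u_pair,
                        dim=2,
                        search_space=cfg.search_space or _VINE_SEARCH_SPACE,
                        n_trials=cfg.n_trials,
                        seed=int(next(fit_seeds).generate_state(1)[0] % 2**31),
                        train_cfg=cfg.train_cfg or VINE_TRAIN_CFG,
                    )
                    fit_seconds = time.time() - t0
                    sd = [int(next(eval_seeds).generate_state(1)[0] % 2**31) for _ in range(2)]
                    draws = flow.sample(n_eval, seed=sd[0])
                    gt_draws = np.column_stack([curr_gt[:, i], root_gt])
                    kl = kl_knn(draws, gt_draws, k=5)
                    ent = copula_entropy_mc(flow, K=n_eval, seed=sd[1])
                    ks_max = max(
                        stats.kstest(draws[:, c], "uniform").statistic for c in range(2)
                    )
                    rows.append(
                        {
                            "estimator": "nsf",
                            "case": case.label(),
                            "family": case.family,
                            "strength": case.strength,
                            "dim": case.dim,
                            "data_type": case.data_type,
                            "repetition": rep,
                            "tree": j + 1,
                            "pair": i - j,
                            "kl_nats": kl.value,
                            "entropy_bits": ent.value,
                            "ks_max": ks_max,
                            "fit_seconds": fit_seconds,
                        }
                    )
                if j < d - 2:
                    for i in range(j + 1, d):
                        curr[:, i] = np.clip(
                            copula_hfunc(case.spec, curr[:, i], rootcol), CLAMP_EPS, 1 - CLAMP_EPS
                        )
                        curr_gt[:, i] = np.clip(
                            copula_hfunc(case.spec, curr_gt[:, i], root_gt), CLAMP_EPS, 1 - CLAMP_EPS
                        )
    return pd.DataFrame(rows)


def aggregate_results(table: pd.DataFrame) -> pd.DataFrame:
    """Per-case medians/IQRs of KL and entropy plus the Spearman correlation
    between the two (the KL-vs-entropy relationship)."""
    if len(table) == 0:
        raise ValueError("empty results table")

    def _agg(g: pd.DataFrame) -> pd.Series:
        kl, ent = g["kl_nats"], g["entropy_bits"]
        if len(g) > 2 and kl.nunique() > 1 and ent.nunique() > 1:
            rho = stats.spearmanr(kl, ent).statistic
        else:
            rho = np.nan
        return pd.Series(
            {
                "n_rows": len(g),
                "kl_median": kl.median(),
                "kl_iqr": kl.quantile(0.75) - kl.quantile(0.25),
                "entropy_median": ent.median(),
                "entropy_iqr": ent.quantile(0.75) - ent.quantile(0.25),
                "spearman_kl_entropy": rho,
            }
        )

    return table.groupby("case").apply(_agg, include_groups=False).reset_index()


# -- synthetic V1-like fixture ------------------------------------------------

CORRIDOR_CM = 160.0
REWARD_ZONE = (120.0, 140.0)


def generate_v1_like_fixture(n_trials: int, n_units: int = 5, seed=None):
    """Simulate a virtual-corridor session: position traces, position-tuned
    Poisson spiking entangled by a heavy-tailed (Clayton theta=5) latent
    copula, licking concentrated in the reward zone and running speed that
    drops there.

    Returns (events, behavior): long-format DataFrames
    ``(trial, unit, time_s, position_cm, spikes)`` and
    ``(trial, time_s, position_cm, speed_cm_s, licks)`` sampled on a 100 ms
    grid.
    """
    if n_trials < 10:
        raise ValueError("need at least 10 trials")
    rng = np.random.default_rng(seed)
    dt = 0.1
    # unit tuning: three reward-zone units, the rest tuned earlier in the corridor
    centers = np.array([130.0, 128.0, 135.0, 60.0, 90.0])[:n_units]
    widths = np.array([12.0, 14.0, 12.0, 25.0, 25.0])[:n_units]
    peak_hz = np.array([28.0, 24.0, 22.0, 18.0, 16.0])[:n_units]
    gain_spec = ParametricCopulaSpec("clayton", theta=5.0)

    ev_rows, beh_rows = [], []
    n_rz = int(np.sum((centers >= REWARD_ZONE[0]) & (centers <= REWARD_ZONE[1])))
    for trial in range(n_trials):
        # trial-level multiplicative gains, entangled across units
        u = copula_sample(gain_spec, max(n_units, 2), seed=rng)[:, 0][:n_units]
        gains = stats.gamma(4.0).ppf(u) / 4.0
        # the shared reward-zone excitability also drives licking and slows running
        g_rz = gains[:n_rz].mean() if n_rz else gains.mean()
        pos = 0.0
        t = 0.0
        while pos < CORRIDOR_CM:
            in_rz = REWARD_ZONE[0] <= pos <= REWARD_ZONE[1]
            base_speed = max(12.0 - 4.0 * g_rz, 3.0) if in_rz else 35.0
            speed = max(rng.normal(base_speed, 4.0), 2.0)
            rates = peak_hz * np.exp(-0.5 * ((pos - centers) / widths) ** 2) * gains
            spikes = rng.poisson(rates * dt)
            lick_hz = 2.0 if not in_rz else 8.0 + 20.0 * g_rz
            licks = rng.poisson(lick_hz * dt)
            if in_rz and licks > 0:
                speed = max(speed - 4.0 * licks, 1.0)
            for unit in range(n_units):
                if spikes[unit] > 0:
                    ev_rows.append((trial, unit, round(t, 3), round(pos, 3), int(spikes[unit])))
            beh_rows.append((trial, round(t, 3), round(pos, 3), speed, int(licks)))
            pos += speed * dt
            t += dt
    events = pd.DataFrame(ev_rows, columns=["trial", "unit", "time_s", "position_cm", "spikes"])
    behavior = pd.DataFrame(beh_rows, columns=["trial", "time_s", "position_cm", "speed_cm_s", "licks"])
    return events, behavior


def reward_times(behavior: pd.DataFrame) -> dict:
    """Per-trial reward acquisition time: first lick inside the reward zone.

    Trials without an in-zone lick are omitted (unsuccessful trials)."""
    out = {}
    in_zone = behavior[
        (behavior.position_cm >= REWARD_ZONE[0])
        & (behavior.position_cm <= REWARD_ZONE[1])
        & (behavior.licks > 0)
    ]
    for trial, g in in_zone.groupby("trial"):
        out[int(trial)] = float(g.time_s.min())
    return out
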