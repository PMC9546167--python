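"""Spike binning and dependence-module selection.

Spike-event tables (long format: trial, unit, time_s, position_cm, spikes)
are binned into trials x bins x units count tensors either along corridor
position (20 cm default) or in a window around a per-trial event such as
reward delivery (300 ms default).  ``select_module`` then picks a subset of
units whose pairwise rank dependence all exceeds a Kendall-tau threshold,
the criterion used to pick out co-dependent cell modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .information import kendall_tau_empirical

__all__ = ["BinnedCounts", "bin_spikes_position", "bin_spikes_event", "select_module"]

logger = logging.getLogger("vineflow")


class EmptySelectionError(ValueError):
    pass


@dataclass
class BinnedCounts:
    """trials x bins x units spike-count tensor with aligned bin edges."""

    counts: np.ndarray
    bin_edges: np.ndarray
    axis: str  # "position" or "time_from_event"
    unit_ids: np.ndarray
    trial_ids: np.ndarray

    def __post_init__(self):
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.counts.shape[1] != len(self.bin_edges) - 1:
            raise ValueError("counts/bin_edges shape mismatch")

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def pooled(self, pool: str = "both") -> np.ndarray:
        """Observations x units matrix for copula fitting.

        pool="both" treats every (trial, bin) cell as one observation;
        "trial" sums over bins per trial; "bin" sums over trials per bin.
        """
        if pool == "both":
            return self.counts.reshape(-1, self.counts.shape[2])
        if pool == "trial":
            return self.counts.sum(axis=1)
        if pool == "bin":
            return self.counts.sum(axis=0)
        raise ValueError("pool must be 'both', 'trial' or 'bin'")


def _bin_counts(events: pd.DataFrame, values: np.ndarray, edges: np.ndarray,
                axis: str, trial_ids, unit_ids) -> BinnedCounts:
    trial_ids = np.asarray(sorted(trial_ids))
    unit_ids = np.asarray(sorted(unit_ids))
    t_index = {t: i for i, t in enumerate(trial_ids)}
    u_index = {u: i for i, u in enumerate(unit_ids)}
    counts = np.zeros((len(trial_ids), len(edges) - 1, len(unit_ids)), dtype=np.int64)
    in_range = (values >= edges[0]) & (values <= edges[-1])
    n_dropped = int(events.loc[~in_range, "spikes"].sum()) if (~in_range).any() else 0
    if n_dropped:
        logger.warning("%d spikes outside the binning range were dropped", n_dropped)
    ev = events.loc[in_range]
    vals = values[in_range]
    # half-open bins [a, b); the last bin is closed
    idx = np.minimum(np.searchsorted(edges, vals, side="right") - 1, len(edges) - 2)
    for (t, u), (b, s) in zip(
        zip(ev["trial"].to_numpy(), ev["unit"].to_numpy()),
        zip(idx, ev["spikes"].to_numpy()),
    ):
        if t in t_index:
            counts[t_index[t], b, u_index[u]] += int(s)
    return BinnedCounts(counts=counts, bin_edges=edges, axis=axis,
                        unit_ids=unit_ids, trial_ids=trial_ids)


def bin_spikes_position(
    events: pd.DataFrame, corridor_length_cm: float = 160.0, bin_cm: float = 20.0
) -> BinnedCounts:
    """Bin spike events by corridor position (default 20 cm bins)."""
    n_bins = int(round(corridor_length_cm / bin_cm))
    edges = np.linspace(0.0, corridor_length_cm, n_bins + 1)
    return _bin_counts(
        events,
        events["position_cm"].to_numpy(dtype=float),
        edges,
        "position",
        events["trial"].unique(),
        events["unit"].unique(),
    )


def bin_spikes_event(
    events: pd.DataFrame,
    event_times: Mapping[int, float],
    window_s: float = 3.5,
    bin_s: float = 0.3,
) -> BinnedCounts:
    """Bin spikes relative to a per-trial event (reward) time.

    Bins tile the window [-window_s, +window_s); when the window is not a
    multiple of the bin width the residual is dropped symmetrically (7 s at
    300 ms gives 23 bins covering [-3.45, 3.45)).  Trials without an event
    time are excluded and logged.
    """
    n_bins = int(np.floor(2.0 * window_s / bin_s))
    half_span = n_bins * bin_s / 2.0
    edges = -half_span + bin_s * np.arange(n_bins + 1)
    trials_all = events["trial"].unique()
    eligible = [t for t in trials_all if t in event_times]
    skipped = set(trials_all) - set(eligible)
    if skipped:
        logger.info("excluding %d trials without an event time", len(skipped))
    if not eligible:
        raise EmptySelectionError("no trials with an event time")
    ev = events[events["trial"].isin(eligible)].copy()
    rel = ev["time_s"].to_numpy(dtype=float) - np.array(
        [event_times[t] for t in ev["trial"]]
    )
    return _bin_counts(ev, rel, edges, "time_from_event", eligible, events["unit"].unique())


def select_module(counts: np.ndarray, tau_threshold: float = 0.3) -> list:
    """Pick a module: units that are all pairwise rank-dependent.

    Greedy clique growth on the |Kendall tau-b| > threshold graph, seeded by
    the unit with the largest total |tau| and extended in decreasing-score
    order (ties broken by column index).  Returns the selected column
    indices, possibly empty.
    """
    counts = np.asarray(counts, dtype=float)
    n_units = counts.shape[1]
    if n_units < 2:
        raise ValueError("need at least 2 units")
    tau = np.zeros((n_units, n_units))
    for i, j in combinations(range(n_units), 2):
        try:
            t = kendall_tau_empirical(counts[:, i], counts[:, j])
        except ValueError:
            t = 0.0
        tau[i, j] = tau[j, i] = 0.0 if np.isnan(t) else t
    ok = np.abs(tau) > tau_threshold
    scores = np.abs(tau).sum(axis=1)
    order = np.lexsort((np.arange(n_units), -scores))
    seed = next((int(i) for i in order if ok[i].any()), None)
    if seed is None:
        return []
    module = [seed]
    for cand in order:
        if cand != seed and all(ok[cand, m] for m in module):
            module.append(int(cand))
    return sorted(module)
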