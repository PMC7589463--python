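"""Bootstrap feature selection: five ranking methods.

Each method scores every feature on each of ``n_bootstrap`` resamples of
the exploratory cohort; per-bootstrap scores become ranks and the final
ordering is by mean rank (ties broken by feature name).

Methods
-------
spearman : |Spearman rho| between the feature and the event time among
    patients with an observed event.
mim : mutual information between the equal-frequency 4-binned feature and
    the event indicator.
mifs : greedy forward MI selection with total-redundancy penalty
    (beta = 1).
mrmr : greedy forward MI selection with mean-redundancy penalty.
rfvi : permutation variable importance of a random survival forest.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import mutual_info_score
from sksurv.ensemble import RandomSurvivalForest
from sksurv.util import Surv

__all__ = ["SELECTORS", "rank_features", "selector_scores"]

log = logging.getLogger(__name__)

SELECTORS = ("spearman", "mim", "mifs", "mrmr", "rfvi")

N_MI_BINS = 4
#: greedy MI selectors stop ordering after this many picks; the remainder
#: is ranked by plain relevance
MAX_GREEDY = 30


def _bin_equal_freq(x: np.ndarray, n_bins: int = N_MI_BINS) -> np.ndarray:
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(qs, x, side="right")


def _mi_matrix_with_target(Xb: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.array([mutual_info_score(Xb[:, j], y)
                     for j in range(Xb.shape[1])])


def _greedy_mi_order(Xb: np.ndarray, y: np.ndarray,
                     penalty: str) -> np.ndarray:
    """Selection order of a greedy forward MI scheme; returns ranks."""
    p = Xb.shape[1]
    relevance = _mi_matrix_with_target(Xb, y)
    selected: list[int] = []
    remaining = set(range(p))
    red_sum = np.zeros(p)
    n_steps = min(p, MAX_GREEDY)
    for _ in range(n_steps):
        if not selected:
            crit = relevance.copy()
        else:
            if penalty == "mifs":
                crit = relevance - red_sum
            else:  # mrmr
                crit = relevance - red_sum / len(selected)
        crit_masked = np.where(
            [j in remaining for j in range(p)], crit, -np.inf)
        j_star = int(np.argmax(crit_masked))
        selected.append(j_star)
        remaining.discard(j_star)
        mi_j = np.array([mutual_info_score(Xb[:, j], Xb[:, j_star])
                         for j in range(p)])
        red_sum += mi_j
    ranks = np.full(p, np.nan)
    for r, j in enumerate(selected):
        ranks[j] = r
    if remaining:
        rest = sorted(remaining, key=lambda j: -relevance[j])
        for r, j in enumerate(rest):
            ranks[j] = n_steps + r
    return ranks


def selector_scores(selector: str, X: np.ndarray, time: np.ndarray,
                    event: np.ndarray, rng: np.random.Generator
                    ) -> np.ndarray:
    """Per-feature *ranks* (0 = best) on one sample for one method."""
    p = X.shape[1]
    if selector == "spearman":
        ev = event.astype(bool)
        if ev.sum() < 3:
            return np.zeros(p)
        scores = np.array([abs(spearmanr(X[ev, j], time[ev]).statistic)
                           for j in range(p)])
        scores = np.nan_to_num(scores)
        return _scores_to_ranks(scores)
    Xb = np.column_stack([_bin_equal_freq(X[:, j]) for j in range(p)])
    if selector == "mim":
        return _scores_to_ranks(_mi_matrix_with_target(Xb, event))
    if selector == "mifs":
        return _greedy_mi_order(Xb, event, "mifs")
    if selector == "mrmr":
        return _greedy_mi_order(Xb, event, "mrmr")
    if selector == "rfvi":
        return _rfvi_ranks(X, time, event, rng)
    raise ValueError(f"unknown selector {selector!r}")


def _scores_to_ranks(scores: np.ndarray) -> np.ndarray:
    order = np.argsort(-scores, kind="stable")
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(order.size)
    return ranks


def _rfvi_ranks(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    y = Surv.from_arrays(event.astype(bool), time)
    seed = int(rng.integers(0, 2**31 - 1))
    rsf = RandomSurvivalForest(n_estimators=25, min_samples_leaf=10,
                               max_features="sqrt", random_state=seed,
                               n_jobs=1)
    rsf.fit(X, y)
    base = rsf.score(X, y)
    perm_rng = np.random.default_rng(seed)
    imp = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        Xp = X.copy()
        Xp[:, j] = perm_rng.permutation(Xp[:, j])
        imp[j] = base - rsf.score(Xp, y)
    return _scores_to_ranks(imp)


def rank_features(selector: str, table: pd.DataFrame, time: np.ndarray,
                  event: np.ndarray, n_bootstrap: int = 1000,
                  seed: int = 0) -> list[str]:
    """Final feature ordering by mean rank over bootstrap resamples."""
    if selector not in SELECTORS:
        raise ValueError(f"unknown selector {selector!r}; "
                         f"choose from {SELECTORS}")
    X = table.to_numpy(dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    rank_sum = np.zeros(X.shape[1])
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        if event[idx].sum() == 0:
            idx = np.arange(n)  # degenerate resample: fall back, logged
            log.debug("bootstrap %d all-censored; using full sample", b)
        rank_sum += selector_scores(selector, X[idx], time[idx],
                                    event[idx], rng)
    mean_rank = rank_sum / n_bootstrap
    order = sorted(range(X.shape[1]),
                   key=lambda j: (mean_rank[j], table.columns[j]))
    return [table.columns[j] for j in order]
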