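"""The six survival learners behind a common fit/predict_risk surface.

Every learner predicts a real-valued risk score oriented *higher = higher
hazard* of the event:

* ``cox``        — Cox proportional hazards (partial-likelihood linear
                   predictor), small ridge penalty for stability.
* ``bt-cox``     — gradient boosting of the Cox partial likelihood with
                   shallow regression-tree base learners.
* ``bglm-cox``   — the same loss with componentwise linear base learners.
* ``rsf``        — random survival forest; risk = cumulative-hazard
                   summary ("ensemble mortality").
* ``msr-rf``     — survival forest whose splits maximise the maximally
                   selected standardised log-rank statistic.
* ``bt-weibull`` — gradient boosting of the full parametric Weibull
                   accelerated-failure-time log-likelihood; risk is the
                   negated predicted log event time, which unifies the
                   higher-is-worse convention.

``cox``/``bt-cox``/``bglm-cox``/``rsf`` wrap scikit-survival estimators;
``msr-rf`` and ``bt-weibull`` are implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.tree import DecisionTreeRegressor
from sksurv.ensemble import (ComponentwiseGradientBoostingSurvivalAnalysis,
                             GradientBoostingSurvivalAnalysis,
                             RandomSurvivalForest)
from sksurv.linear_model import CoxPHSurvivalAnalysis
from sksurv.util import Surv

__all__ = ["LEARNERS", "make_learner", "MaxStatSurvivalForest",
           "BoostedWeibullAFT"]

log = logging.getLogger(__name__)

LEARNERS = ("cox", "bt-cox", "bglm-cox", "rsf", "msr-rf", "bt-weibull")


class _SksurvWrapper:
    """Adapter exposing fit(X, time, event) / predict_risk(X)."""

    def __init__(self, est):
        self.est = est

    def fit(self, X, time, event):
        y = Surv.from_arrays(np.asarray(event, dtype=bool),
                             np.asarray(time, dtype=float))
        self.est.fit(np.asarray(X, dtype=float), y)
        return self

    def predict_risk(self, X) -> np.ndarray:
        return np.asarray(self.est.predict(np.asarray(X, dtype=float)),
                          dtype=float)


# ------------------------------------------------------------------ msr-rf

def _logrank_scores(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Log-rank scores a_i = delta_i - NelsonAalen(t_i) (Hothorn/Lausen)."""
    order = np.argsort(time, kind="stable")
    t, d = time[order], event[order].astype(float)
    n = t.size
    at_risk = n - np.arange(n)
    # Nelson-Aalen at each ordered time, handling ties via cumulative sums
    na_inc = d / at_risk
    na = np.cumsum(na_inc)
    # tied times share the same cumulative hazard (last of the tie block)
    for i in range(n - 2, -1, -1):
        if t[i] == t[i + 1]:
            na[i] = na[i + 1]
    scores = np.empty(n)
    scores[order] = d - na
    return scores


@dataclass
class _Node:
    feature: int = -1
    threshold: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None
    value: float = 0.0


class MaxStatSurvivalForest:
    """Random survival forest with maximally selected rank statistics.

    Each split maximises the standardised linear log-rank statistic over
    candidate cutpoints restricted to the (10%, 90%) quantile range of the
    feature within the node.  Leaf risk is the node's total Nelson–Aalen
    cumulative hazard; the forest risk is the average over trees.
    """

    def __init__(self, n_estimators: int = 100, min_node: int = 15,
                 min_leaf: int = 5, max_depth: int = 10,
                 mtry: int | None = None, random_state: int = 0):
        self.n_estimators = n_estimators
        self.min_node = min_node
        self.min_leaf = min_leaf
        self.max_depth = max_depth
        self.mtry = mtry
        self.random_state = random_state
        self.trees_: list[_Node] = []

    # -- tree construction
    def _best_split(self, X, time, event, feat_idx):
        n = time.size
        a = _logrank_scores(time, event)
        abar, s2 = a.mean(), a.var(ddof=0)
        if s2 <= 0:
            return None
        best = (0.0, None, None)
        for j in feat_idx:
            x = X[:, j]
            order = np.argsort(x, kind="stable")
            xs, as_ = x[order], a[order]
            csum = np.cumsum(as_)
            m = np.arange(1, n)
            # valid cutpoints: between distinct values, inside leaf bounds
            distinct = xs[:-1] < xs[1:]
            lo, hi = np.quantile(x, [0.1, 0.9])
            valid = (distinct & (m >= self.min_leaf)
                     & (n - m >= self.min_leaf)
                     & (xs[:-1] >= lo) & (xs[:-1] <= hi))
            if not valid.any():
                continue
            sm = csum[:-1]
            var = m * (n - m) / (n - 1.0) * s2
            with np.errstate(divide="ignore", invalid="ignore"):
                stat = np.abs(sm - m * abar) / np.sqrt(var)
            stat = np.where(valid, stat, 0.0)
            k = int(np.argmax(stat))
            if stat[k] > best[0]:
                thr = 0.5 * (xs[k] + xs[k + 1])
                best = (float(stat[k]), j, thr)
        return best if best[1] is not None else None

    def _leaf(self, time, event) -> _Node:
        order = np.argsort(time, kind="stable")
        d = event[order].astype(float)
        at_risk = time.size - np.arange(time.size)
        return _Node(value=float(np.sum(d / at_risk)))

    def _grow(self, X, time, event, rng, depth) -> _Node:
        n = time.size
        if (n < self.min_node or depth >= self.max_depth
                or event.sum() == 0):
            return self._leaf(time, event)
        p = X.shape[1]
        mtry = self.mtry or max(1, int(np.sqrt(p)))
        feat_idx = rng.choice(p, size=min(mtry, p), replace=False)
        split = self._best_split(X, time, event, feat_idx)
        if split is None or split[0] <= 0:
            return self._leaf(time, event)
        _, j, thr = split
        left = X[:, j] <= thr
        node = _Node(feature=j, threshold=thr)
        node.left = self._grow(X[left], time[left], event[left], rng,
                               depth + 1)
        node.right = self._grow(X[~left], time[~left], event[~left], rng,
                                depth + 1)
        return node

    def fit(self, X, time, event):
        X = np.asarray(X, dtype=float)
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        rng = np.random.default_rng(self.random_state)
        self.trees_ = []
        n = time.size
        for _ in range(self.n_estimators):
            idx = rng.integers(0, n, size=n)
            self.trees_.append(self._grow(X[idx], time[idx], event[idx],
                                          rng, 0))
        return self

    def _predict_tree(self, node: _Node, X: np.ndarray) -> np.ndarray:
        if node.feature < 0:
            return np.full(X.shape[0], node.value)
        out = np.empty(X.shape[0])
        left = X[:, node.feature] <= node.threshold
        if left.any():
            out[left] = self._predict_tree(node.left, X[left])
        if (~left).any():
            out[~left] = self._predict_tree(node.right, X[~left])
        return out

    def predict_risk(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.mean([self._predict_tree(t, X) for t in self.trees_],
                       axis=0)


# -------------------------------------------------------------- bt-weibull

class BoostedWeibullAFT:
    """Gradient boosting of the Weibull AFT log-likelihood.

    Model: log T = mu(x) + sigma * W with W standard Gumbel (minimum).
    ``mu`` is boosted with shallow regression trees fitted to the
    log-likelihood gradient; ``sigma`` is refreshed by 1-D maximum
    likelihood each iteration.  Risk = -mu(x) (shorter predicted log
    event time = higher risk).
    """

    def __init__(self, n_estimators: int = 100, learning_rate: float = 0.1,
                 max_depth: int = 2, random_state: int = 0):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.random_state = random_state
        self.mu0_: float = 0.0
        self.sigma_: float = 1.0
        self.trees_: list[DecisionTreeRegressor] = []

    @staticmethod
    def _neg_ll(logt, delta, mu, sigma):
        z = np.clip((logt - mu) / sigma, -30.0, 30.0)
        ll = delta * (z - np.log(sigma)) - np.exp(z)
        return -float(ll.sum())

    def fit(self, X, time, event):
        X = np.asarray(X, dtype=float)
        logt = np.log(np.asarray(time, dtype=float))
        delta = np.asarray(event, dtype=float)
        self.mu0_ = float(logt.mean())
        mu = np.full(logt.size, self.mu0_)
        self.trees_ = []
        self.sigma_ = self._fit_sigma(logt, delta, mu)
        for b in range(self.n_estimators):
            z = np.clip((logt - mu) / self.sigma_, -30.0, 30.0)
            grad = (np.exp(z) - delta) / self.sigma_  # d(loglik)/d(mu)
            tree = DecisionTreeRegressor(
                max_depth=self.max_depth,
                random_state=self.random_state + b)
            tree.fit(X, grad)
            mu = mu + self.learning_rate * tree.predict(X)
            self.trees_.append(tree)
            self.sigma_ = self._fit_sigma(logt, delta, mu)
        return self

    def _fit_sigma(self, logt, delta, mu) -> float:
        res = minimize_scalar(
            lambda s: self._neg_ll(logt, delta, mu, s),
            bounds=(1e-3, 50.0), method="bounded")
        return float(res.x)

    def predict_mu(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        mu = np.full(X.shape[0], self.mu0_)
        for tree in self.trees_:
            mu = mu + self.learning_rate * tree.predict(X)
        return mu

    def predict_risk(self, X) -> np.ndarray:
        return -self.predict_mu(X)


# ----------------------------------------------------------------- factory

def make_learner(name: str, random_state: int = 0, **hp):
    """Instantiate a learner by name with its hyper-parameters."""
    if name == "cox":
        return _SksurvWrapper(CoxPHSurvivalAnalysis(
            alpha=hp.get("alpha", 1e-4)))
    if name == "bt-cox":
        return _SksurvWrapper(GradientBoostingSurvivalAnalysis(
            loss="coxph",
            n_estimators=hp.get("n_estimators", 100),
            learning_rate=hp.get("learning_rate", 0.1),
            max_depth=hp.get("max_depth", 2),
            random_state=random_state))
    if name == "bglm-cox":
        return _SksurvWrapper(ComponentwiseGradientBoostingSurvivalAnalysis(
            loss="coxph",
            n_estimators=hp.get("n_estimators", 100),
            learning_rate=hp.get("learning_rate", 0.3)))
    if name == "rsf":
        return _SksurvWrapper(RandomSurvivalForest(
            n_estimators=hp.get("n_estimators", 100),
            min_samples_leaf=hp.get("min_samples_leaf", 10),
            max_features="sqrt", n_jobs=1, random_state=random_state))
    if name == "msr-rf":
        return MaxStatSurvivalForest(
            n_estimators=hp.get("n_estimators", 100),
            min_node=hp.get("min_node", 15),
            min_leaf=hp.get("min_leaf", 5),
            random_state=random_state)
    if name == "bt-weibull":
        return BoostedWeibullAFT(
            n_estimators=hp.get("n_estimators", 100),
            learning_rate=hp.get("learning_rate", 0.1),
            max_depth=hp.get("max_depth", 2),
            random_state=random_state)
    raise ValueError(f"unknown learner {name!r}; choose from {LEARNERS}")
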