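"""Hyper-parameter tuning, bootstrap ensemble training and prediction."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..evaluation import concordance_index
from .learners import LEARNERS, make_learner
from .preprocess import Preprocessor
from .selectors import SELECTORS, rank_features

__all__ = ["ModelCombo", "EnsembleModel", "tune_hyperparams",
           "train_ensemble", "ensemble_predict", "fit_risk_model",
           "RiskModel", "representative_combo", "HYPER_GRIDS"]

log = logging.getLogger(__name__)

#: random-search grids; signature size k is shared by all learners
HYPER_GRIDS: dict[str, dict[str, list]] = {
    "cox": {"alpha": [1e-6, 1e-4, 1e-2, 1e-1]},
    "bt-cox": {"n_estimators": [50, 100, 200],
               "learning_rate": [0.05, 0.1, 0.2],
               "max_depth": [1, 2, 3]},
    "bglm-cox": {"n_estimators": [50, 100, 200],
                 "learning_rate": [0.1, 0.3, 0.5]},
    "rsf": {"n_estimators": [50, 100],
            "min_samples_leaf": [5, 10, 20]},
    "msr-rf": {"n_estimators": [50, 100],
               "min_node": [10, 15, 30]},
    "bt-weibull": {"n_estimators": [50, 100, 200],
                   "learning_rate": [0.05, 0.1],
                   "max_depth": [1, 2]},
}
MAX_SIGNATURE_SIZE = 10


@dataclass(frozen=True)
class ModelCombo:
    """One of the 5 x 6 feature-selector / learner combinations."""

    selector: str
    learner: str

    def __post_init__(self):
        if self.selector not in SELECTORS:
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.learner not in LEARNERS:
            raise ValueError(f"unknown learner {self.learner!r}")

    def __str__(self) -> str:
        return f"{self.selector}+{self.learner}"


@dataclass
class EnsembleModel:
    """B bootstrap-fitted learners plus everything needed to predict."""

    combo: ModelCombo
    signature: list[str]
    hyperparams: dict
    models: list = field(default_factory=list)
    preprocessor: Preprocessor | None = None

    def __post_init__(self):
        if not self.signature:
            raise ValueError("signature must contain at least one feature")

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return ensemble_predict(self, table)


def _fit_one(combo: ModelCombo, hp: dict, X: np.ndarray, time: np.ndarray,
             event: np.ndarray, seed: int):
    if event.sum() == 0:
        raise ValueError("all-censored sample")
    learner = make_learner(combo.learner, random_state=seed,
                           **{k: v for k, v in hp.items() if k != "k"})
    return learner.fit(X, time, event)


def tune_hyperparams(combo: ModelCombo, table: pd.DataFrame,
                     time: np.ndarray, event: np.ndarray,
                     ranking: list[str], budget: int = 10, seed: int = 0,
                     n_inner: int = 10) -> dict:
    """Random search scored by mean out-of-bag concordance.

    Each candidate draws a signature size ``k`` (1..10) and learner
    hyper-parameters from :data:`HYPER_GRIDS`; it is scored by fitting on
    ``n_inner`` bootstrap resamples and evaluating Harrell's C on the
    out-of-bag patients.  Deterministic given ``seed``.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    grid = HYPER_GRIDS[combo.learner]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    n = len(table)
    k_max = min(MAX_SIGNATURE_SIZE, len(ranking))

    best_hp, best_score = None, -np.inf
    for _ in range(budget):
        hp = {"k": int(rng.integers(1, k_max + 1))}
        hp.update({key: vals[rng.integers(0, len(vals))]
                   for key, vals in grid.items()})
        X = table[ranking[:hp["k"]]].to_numpy(dtype=float)
        scores = []
        for b in range(n_inner):
            idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), idx)
            if oob.size < 3 or event[oob].sum() == 0:
                continue
            try:
                m = _fit_one(combo, hp, X[idx], time[idx], event[idx],
                             seed=int(rng.integers(0, 2**31 - 1)))
            except Exception as exc:
                log.debug("tuning fit failed (%s); skipped", exc)
                continue
            try:
                scores.append(concordance_index(
                    m.predict_risk(X[oob]), time[oob], event[oob]))
            except ValueError:
                continue
        score = float(np.mean(scores)) if scores else -np.inf
        if score > best_score:
            best_score, best_hp = score, hp
    if best_hp is None:  # every candidate failed: fall back to defaults
        best_hp = {"k": min(3, k_max)}
    log.info("%s tuned: %s (OOB C=%.3f)", combo, best_hp, best_score)
    return best_hp


def train_ensemble(combo: ModelCombo, signature: list[str],
                   hyperparams: dict, table: pd.DataFrame,
                   time: np.ndarray, event: np.ndarray,
                   n_bootstrap: int = 1000, seed: int = 0) -> EnsembleModel:
    """Fit B learners on bootstrap resamples of the exploratory cohort.

    Non-convergent or degenerate (all-censored) resamples are dropped
    with a log record; more than 50% failures is an error.
    """
    missing = [c for c in signature if c not in table.columns]
    if missing:
        raise ValueError(f"signature features missing from table: {missing}")
    X = table[signature].to_numpy(dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    models, failures = [], 0
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        try:
            models.append(_fit_one(combo, hyperparams, X[idx], time[idx],
                                   event[idx],
                                   seed=int(rng.integers(0, 2**31 - 1))))
        except Exception as exc:
            failures += 1
            log.info("bootstrap fit %d dropped: %s", b, exc)
    if failures > n_bootstrap / 2:
        raise RuntimeError(
            f"{failures}/{n_bootstrap} bootstrap fits failed for {combo}")
    return EnsembleModel(combo=combo, signature=signature,
                         hyperparams=hyperparams, models=models)


def ensemble_predict(model: EnsembleModel, table: pd.DataFrame) -> np.ndarray:
    """Unweighted mean of the per-bootstrap risk scores."""
    missing = [c for c in model.signature if c not in table.columns]
    if missing:
        raise ValueError(f"missing signature columns: {missing}")
    X = table[model.signature].to_numpy(dtype=float)
    risks = np.stack([m.predict_risk(X) for m in model.models])
    return risks.mean(axis=0)


@dataclass
class RiskModel:
    """A fully fitted pipeline for one ROI and one combo: preprocessing,
    signature, ensemble.  ``predict`` accepts raw feature rows."""

    preprocessor: Preprocessor
    ensemble: EnsembleModel
    ranking: list[str]

    def predict(self, raw_table: pd.DataFrame) -> np.ndarray:
        return self.ensemble.predict(self.preprocessor.transform(raw_table))


def fit_risk_model(combo: ModelCombo, raw_table: pd.DataFrame,
                   time: np.ndarray, event: np.ndarray,
                   n_bootstrap_select: int = 1000,
                   n_bootstrap_train: int = 1000,
                   tune_budget: int = 10, seed: int = 0,
                   signature_size: int | None = None) -> RiskModel:
    """End-to-end steps I-IV on an exploratory feature table.

    ``signature_size`` fixes k and skips tuning (desk-scale shortcut);
    otherwise k comes from the tuned hyper-parameters.
    """
    ss = np.random.SeedSequence(seed)
    s_rank, s_tune, s_train = (int(c.generate_state(1)[0] % (2**31))
                               for c in ss.spawn(3))
    prep = Preprocessor().fit(raw_table)
    table = prep.transform(raw_table)
    ranking = rank_features(combo.selector, table, time, event,
                            n_bootstrap=n_bootstrap_select, seed=s_rank)
    if signature_size is not None:
        hp = {"k": min(signature_size, len(ranking))}
    else:
        hp = tune_hyperparams(combo, table, time, event, ranking,
                              budget=tune_budget, seed=s_tune)
    signature = ranking[:hp["k"]]
    ens = train_ensemble(combo, signature, hp, table, time, event,
                         n_bootstrap=n_bootstrap_train, seed=s_train)
    ens.preprocessor = prep
    return RiskModel(preprocessor=prep, ensemble=ens, ranking=ranking)


def representative_combo(c_matrix: pd.DataFrame) -> tuple[str, str]:
    """Representative (selector, learner) pair from a C-index matrix.

    ``c_matrix`` has selectors as rows and learners as columns.  The
    representative selector is the one whose median C-index over learners
    is closest to the median of those medians (ties: lexicographic name);
    the learner is chosen analogously over columns.
    """
    sel_med = c_matrix.median(axis=1)
    lrn_med = c_matrix.median(axis=0)
    sel_target = sel_med.median()
    lrn_target = lrn_med.median()
    sel = sorted(sel_med.index,
                 key=lambda s: (abs(sel_med[s] - sel_target), s))[0]
    lrn = sorted(lrn_med.index,
                 key=lambda l: (abs(lrn_med[l] - lrn_target), l))[0]
    return sel, lrn
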