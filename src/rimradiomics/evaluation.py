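"""Prognostic performance assessment.

Harrell's concordance index with percentile-bootstrap confidence
intervals, median-risk stratification with Kaplan–Meier curves and
log-rank tests, tumour-volume subgroup analysis (20 cm³ threshold) and a
paired sign-flip permutation test comparing sub-volumes across model
combinations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "concordance_index", "bootstrap_ci", "stratify", "RiskGroups",
    "kaplan_meier", "logrank_test", "subgroup_analysis",
    "compare_subvolumes", "EvaluationResult", "evaluate_model",
]

log = logging.getLogger(__name__)

VOLUME_THRESHOLD_CM3 = 20.0


def concordance_index(risk: np.ndarray, time: np.ndarray,
                      event: np.ndarray) -> float:
    """Harrell's C: fraction of comparable pairs ordered concordantly.

    A pair is comparable when the shorter observed time ends in an event;
    tied risks count 1/2; pairs with tied times where both are events are
    not comparable (neither ordering is wrong).  0.5 = random, 1.0 =
    perfect.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    n = time.size
    if not (risk.size == n == event.size):
        raise ValueError("risk/time/event length mismatch")

    # comparable: t_i < t_j and event_i (patient i fails first)
    ti, tj = time[:, None], time[None, :]
    ri, rj = risk[:, None], risk[None, :]
    comp = (ti < tj) & event[:, None]
    n_comp = int(comp.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs under censoring")
    conc = float(np.sum(comp & (ri > rj)))
    ties = float(np.sum(comp & (ri == rj)))
    return (conc + 0.5 * ties) / n_comp


def bootstrap_ci(metric, data: tuple[np.ndarray, ...], n_boot: int = 1000,
                 level: float = 0.95, seed: int = 0
                 ) -> tuple[float, float]:
    """Percentile bootstrap interval for ``metric(*resampled(data))``.

    ``data`` is a tuple of aligned per-patient arrays resampled jointly.
    Degenerate resamples on which the metric raises are skipped (logged).
    """
    n = len(data[0])
    if n < 10:
        raise ValueError("bootstrap CI needs at least 10 patients")
    rng = np.random.default_rng(seed)
    vals = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            vals.append(metric(*(np.asarray(d)[idx] for d in data)))
        except ValueError:
            skipped += 1
    if skipped:
        log.info("bootstrap CI: %d/%d degenerate resamples skipped",
                 skipped, n_boot)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(vals, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


@dataclass
class RiskGroups:
    """Median-risk dichotomisation fitted on the exploratory cohort."""

    cutoff: float
    exploratory: np.ndarray  # bool, True = high risk
    validation: np.ndarray


def stratify(risk_explor: np.ndarray,
             risk_valid: np.ndarray) -> RiskGroups:
    """Split patients at the exploratory median risk (<= median -> low).

    The cut-off is computed on exploratory predictions only and applied
    unchanged to the validation cohort.
    """
    risk_explor = np.asarray(risk_explor, dtype=float)
    if risk_explor.size == 0:
        raise ValueError("empty exploratory risks")
    cutoff = float(np.median(risk_explor))
    groups = RiskGroups(cutoff=cutoff,
                        exploratory=risk_explor > cutoff,
                        validation=np.asarray(risk_valid) > cutoff)
    for label, g in (("exploratory", groups.exploratory),
                     ("validation", groups.validation)):
        if g.size and (g.all() or not g.any()):
            log.warning("all %s patients in one risk group; log-rank "
                        "undefined", label)
    return groups


def kaplan_meier(time: np.ndarray, event: np.ndarray,
                 group: np.ndarray) -> dict[str, pd.DataFrame]:
    """Product-limit survival curve per group.

    Returns, per group label, a DataFrame with columns ``time`` and
    ``survival`` (step function; starts at S(0)=1).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    group = np.asarray(group)
    out: dict[str, pd.DataFrame] = {}
    for g in np.unique(group):
        sel = group == g
        if sel.sum() == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel])
        sf = kmf.survival_function_
        out[str(g)] = pd.DataFrame({
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float)})
    return out


def logrank_test(time: np.ndarray, event: np.ndarray,
                 group: np.ndarray) -> float:
    """Two-group log-rank chi-square (1 df) p-value."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, "
                         f"got {labels.size}")
    a = group == labels[0]
    res = _ll_logrank(time[a], time[~a], event_observed_A=event[a],
                      event_observed_B=event[~a])
    return float(res.p_value)


@dataclass
class EvaluationResult:
    combo: str
    roi: str
    cohort: str
    c_index: float
    ci95: tuple[float, float] | None = None
    logrank_p: float | None = None
    subgroups: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.c_index <= 1.0:
            raise ValueError(f"C-index {self.c_index} outside [0, 1]")


def subgroup_analysis(risk: np.ndarray, time: np.ndarray,
                      event: np.ndarray, volumes_cm3: np.ndarray,
                      threshold: float = VOLUME_THRESHOLD_CM3
                      ) -> dict[str, float]:
    """C-index recomputed on the <=threshold and >threshold subgroups."""
    volumes = np.asarray(volumes_cm3, dtype=float)
    out: dict[str, float] = {}
    for label, sel in (("small", volumes <= threshold),
                       ("large", volumes > threshold)):
        if sel.sum() == 0:
            log.info("volume subgroup %r empty; omitted", label)
            continue
        try:
            out[label] = concordance_index(np.asarray(risk)[sel],
                                           time[sel], event[sel])
        except ValueError:
            log.info("volume subgroup %r has no comparable pairs; omitted",
                     label)
    return out


def compare_subvolumes(c_a: np.ndarray, c_b: np.ndarray,
                       n_perm: int = 10_000, seed: int = 0) -> float:
    """Paired sign-flip permutation test on per-combo C-index differences.

    Observed statistic: mean(c_a - c_b) over model combinations.  Null:
    each difference's sign is flipped independently (the sub-volume label
    is exchangeable within a combo); two-sided p with add-one smoothing.
    """
    c_a = np.asarray(c_a, dtype=float)
    c_b = np.asarray(c_b, dtype=float)
    if c_a.size != c_b.size or c_a.size < 2:
        raise ValueError("need >= 2 paired combo evaluations")
    d = c_a - c_b
    obs = abs(d.mean())
    if np.all(d == 0):
        return 1.0
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, d.size))
    null = np.abs((signs * d).mean(axis=1))
    return float((1 + np.sum(null >= obs - 1e-12)) / (1 + n_perm))


def evaluate_model(risk_explor, risk_valid, surv_explor, surv_valid,
                   volumes_valid=None, combo: str = "", roi: str = "",
                   n_boot: int = 1000, seed: int = 0
                   ) -> list[EvaluationResult]:
    """Full assessment of one fitted model: C (with CI), stratified
    log-rank on both cohorts, volume subgroups on validation.

    ``surv_*`` are (time, event) tuples.
    """
    t_e, d_e = (np.asarray(a) for a in surv_explor)
    t_v, d_v = (np.asarray(a) for a in surv_valid)
    groups = stratify(risk_explor, risk_valid)
    results = []
    for cohort, risk, t, d, grp in (
            ("exploratory", risk_explor, t_e, d_e, groups.exploratory),
            ("validation", risk_valid, t_v, d_v, groups.validation)):
        c = concordance_index(risk, t, d)
        try:
            ci = bootstrap_ci(concordance_index, (np.asarray(risk), t, d),
                              n_boot=n_boot, seed=seed)
        except ValueError:
            log.info("cohort %s too small for a bootstrap CI", cohort)
            ci = (float("nan"), float("nan"))
        try:
            p = logrank_test(t, d, grp.astype(int))
        except ValueError:
            p = float("nan")
        res = EvaluationResult(combo=combo, roi=roi, cohort=cohort,
                               c_index=c, ci95=ci, logrank_p=p)
        if cohort == "validation" and volumes_valid is not None:
            res.subgroups = subgroup_analysis(risk, t, d, volumes_valid)
        results.append(res)
    return results
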