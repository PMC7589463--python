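"""Feature pre-processing: z-scoring and correlation clustering.

Features are standardised with exploratory-cohort mean and SD.  Highly
correlated features (|Spearman rho| >= 0.90, complete linkage on the
1 - |rho| distance) are merged into *meta-features*: the mean of the
member z-scores.  Validation rows are transformed with the exploratory
statistics and cluster map only — no leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

__all__ = ["Preprocessor", "preprocess"]

log = logging.getLogger(__name__)

CORR_THRESHOLD = 0.90


def _spearman_abs(X: np.ndarray) -> np.ndarray:
    r = np.apply_along_axis(rankdata, 0, X)
    r = (r - r.mean(axis=0)) / r.std(axis=0)
    return np.abs(r.T @ r) / X.shape[0]


@dataclass
class Preprocessor:
    corr_threshold: float = CORR_THRESHOLD
    means_: pd.Series | None = None
    sds_: pd.Series | None = None
    clusters_: dict[str, list[str]] = field(default_factory=dict)
    columns_: list[str] | None = None

    def fit(self, table: pd.DataFrame) -> "Preprocessor":
        if len(table) < 2:
            raise ValueError("need at least 2 exploratory rows to fit")
        means = table.mean(axis=0)
        sds = table.std(axis=0, ddof=0)
        keep = sds > 0
        dropped = list(table.columns[~keep])
        if dropped:
            log.info("dropping %d zero-variance features (e.g. %s)",
                     len(dropped), dropped[:3])
        cols = list(table.columns[keep])
        self.means_, self.sds_ = means[cols], sds[cols]

        z = ((table[cols] - self.means_) / self.sds_).to_numpy()
        labels = self._cluster(z, cols)
        self.clusters_ = labels
        self.columns_ = list(labels)
        return self

    def _cluster(self, z: np.ndarray, cols: list[str]
                 ) -> dict[str, list[str]]:
        if len(cols) < 2:
            return {c: [c] for c in cols}
        corr = np.clip(_spearman_abs(z), 0.0, 1.0)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        link = hierarchy.linkage(squareform(dist, checks=False),
                                 method="complete")
        # complete linkage at distance <= 1 - threshold keeps every merged
        # pair at |rho| >= threshold
        assign = hierarchy.fcluster(link, t=1.0 - self.corr_threshold,
                                    criterion="distance")
        out: dict[str, list[str]] = {}
        for cid in np.unique(assign):
            members = sorted(np.asarray(cols)[assign == cid].tolist())
            if len(members) == 1:
                out[members[0]] = members
            else:
                out[f"meta_{members[0]}"] = members
        # deterministic column order: by name
        return dict(sorted(out.items()))

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.columns_ is None:
            raise RuntimeError("Preprocessor not fitted")
        z = (table[self.means_.index] - self.means_) / self.sds_
        data = {name: z[members].mean(axis=1)
                for name, members in self.clusters_.items()}
        return pd.DataFrame(data, index=table.index)[self.columns_]

    def fit_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return self.fit(table).transform(table)


def preprocess(table: pd.DataFrame, exploratory_ids,
               corr_threshold: float = CORR_THRESHOLD
               ) -> tuple[pd.DataFrame, Preprocessor]:
    """Fit on the exploratory rows; transform the full table.

    Returns the transformed table (meta-feature columns) and the fitted
    :class:`Preprocessor` (which holds the cluster map).
    """
    prep = Preprocessor(corr_threshold=corr_threshold)
    prep.fit(table.loc[exploratory_ids])
    return prep.transform(table), prep
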