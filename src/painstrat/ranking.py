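"""Feature importance: supervised case/control weighting and unsupervised
Laplacian-score ranking within cases.

The random-forest weighting quantifies how much each variable helps to
separate cases from controls (permutation importance of a forest fit on
the unit-scaled table).  The Laplacian score then ranks the surviving
variables among cases only: a k-nearest-neighbour graph with heat-kernel
weights is built over participants, and each demeaned feature is scored by
how well it respects that local geometry.  Smaller scores indicate
stronger locality preservation, i.e. features that carry the structure
along which the cases naturally split; ``rank_order`` therefore sorts
ascending by score for the Laplacian method and descending for the forest.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .data import FeatureTable
from .errors import ContractError


class RankMethod(str, Enum):
    RF_IMPORTANCE = "rf_importance"
    LAPLACIAN = "laplacian"


@dataclass
class ImportanceRanking:
    method: RankMethod
    scores: pd.Series  # index: variable name
    rank_order: list[str]  # most important first

    def __post_init__(self):
        if sorted(self.rank_order) != sorted(self.scores.index):
            raise ContractError("rank_order must be a permutation of scored variables")

    def top(self, n: int) -> list[str]:
        return self.rank_order[:n]


def rf_feature_weighting(
    table: FeatureTable,
    n_estimators: int = 500,
    n_permutation_repeats: int = 50,
    seed: int = 0,
) -> ImportanceRanking:
    """Permutation importance of a random forest separating case/control.

    The forest uses square-root feature subsampling; importances are the
    mean accuracy drop over ``n_permutation_repeats`` column shuffles,
    evaluated in-sample (the weighting is exploratory, not a validated
    classifier).  Fully deterministic for a fixed seed.
    """
    labels = table.group.to_numpy()
    if len(np.unique(labels)) < 2:
        raise ContractError("both case and control labels are required")
    X = table.data.to_numpy(dtype=float)
    complete = ~np.isnan(X).any(axis=1)
    X, y = X[complete], labels[complete]
    rf = RandomForestClassifier(
        n_estimators=n_estimators, max_features="sqrt", random_state=seed
    )
    rf.fit(X, y)
    imp = permutation_importance(
        rf, X, y, n_repeats=n_permutation_repeats, random_state=seed
    )
    scores = pd.Series(imp.importances_mean, index=table.variables, name="rf_importance")
    order = scores.sort_values(ascending=False, kind="stable").index.tolist()
    return ImportanceRanking(RankMethod.RF_IMPORTANCE, scores, order)


def _knn_heat_affinity(X: np.ndarray, k: int, bandwidth: float | None) -> np.ndarray:
    d2 = squareform(pdist(X, metric="sqeuclidean"))
    n = X.shape[0]
    if bandwidth is None:
        off = d2[~np.eye(n, dtype=bool)]
        bandwidth = float(off.mean()) if off.size else 1.0
    if bandwidth <= 0:
        bandwidth = 1.0  # all points coincide; any constant kernel works
    # k nearest neighbours excluding self, symmetrised by union
    neigh = np.argsort(d2 + np.diag(np.full(n, np.inf)), axis=1)[:, :k]
    adj = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    adj[rows, neigh.ravel()] = True
    adj |= adj.T
    S = np.where(adj, np.exp(-d2 / bandwidth), 0.0)
    return S


def laplacian_rank(
    table: FeatureTable,
    k_neighbours: int = 5,
    bandwidth: float | None = None,
    candidates: list[str] | None = None,
) -> ImportanceRanking:
    """Laplacian score of each feature over a kNN heat-kernel graph.

    For affinity S with degree D and Laplacian L = D - S, each feature f is
    demeaned with D-weights and scored as (f'Lf)/(f'Df).  A feature that is
    constant across participants has no local variation to preserve and is
    assigned +inf, i.e. the least-informative position.  ``bandwidth=None``
    uses the mean pairwise squared Euclidean distance.
    """
    names = candidates if candidates is not None else table.variables
    sub = table.subset_columns(list(names))
    X = sub.data.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ContractError("missing values are not allowed in Laplacian ranking")
    n = X.shape[0]
    if k_neighbours < 1 or k_neighbours >= n:
        raise ContractError(f"k_neighbours must be in [1, {n - 1}] for {n} participants")

    S = _knn_heat_affinity(X, k_neighbours, bandwidth)
    d = S.sum(axis=1)
    D_total = d.sum()
    scores = {}
    for j, name in enumerate(sub.variables):
        f = X[:, j]
        f_t = f - (f @ d) / D_total
        denom = f_t @ (d * f_t)
        if denom <= 1e-15:
            scores[name] = np.inf
            continue
        numer = f_t @ (d * f_t) - f_t @ (S @ f_t)  # f'Lf with L = D - S
        scores[name] = float(numer / denom)
    series = pd.Series(scores, name="laplacian_score")[list(sub.variables)]
    order = series.sort_values(ascending=True, kind="stable").index.tolist()
    return ImportanceRanking(RankMethod.LAPLACIAN, series, order)
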