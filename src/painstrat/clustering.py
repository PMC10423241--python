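"""Cluster-validity scanning and fuzzy c-means sub-grouping.

The scan adds features one at a time in ranked importance order and, at
each feature count, evaluates k-means partitions over a range of cluster
numbers with three validity indices (Calinski-Harabasz, Davies-Bouldin,
Silhouette).  Scanning stops at the first feature count where fewer than
two of the three indices improve at their own best k; the previous count
is selected, and the cluster number is the silhouette-maximising k at that
count (ties to the smaller k).

Sub-groups are then derived by fuzzy c-means: each participant receives a
graded membership to every cluster, controlled by the fuzzifier exponent
m > 1; hard labels are the maximal membership, and cluster ids are
relabelled by descending cluster size so outputs are deterministic.
Cluster-quality metrics (within/between distances on the unit scale,
silhouette, a log-scaled density contrast) are attached afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .data import FeatureTable
from .errors import ContractError
from .ranking import ImportanceRanking

_D2_FLOOR = 1e-12


@dataclass
class ClusterValidityReport:
    grid: pd.DataFrame  # columns: n_features, k, calinski_harabasz, davies_bouldin, silhouette
    selected_n_features: int
    selected_k: int
    selected_features: list[str]
    stop_reason: str
    confident: bool  # silhouette at the selection reaches the confidence floor

    def at(self, n_features: int, k: int) -> pd.Series:
        g = self.grid
        row = g[(g["n_features"] == n_features) & (g["k"] == k)]
        if row.empty:
            raise KeyError((n_features, k))
        return row.iloc[0]


@dataclass
class ClusterModel:
    feature_names: list[str]
    fuzzifier: float
    centroids: pd.DataFrame  # clusters x features, unit scale
    membership: pd.DataFrame  # participants x clusters
    hard_labels: pd.Series  # participant -> cluster id (0 = largest cluster)
    objective: float
    objective_history: list[float]
    converged: bool
    n_iter: int
    within_cluster_distances: dict[int, float] = field(default_factory=dict)
    between_cluster_distance: float = np.nan
    silhouette_index: float = np.nan
    discrimination_value: float = np.nan

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def cluster_sizes(self) -> dict[int, int]:
        return self.hard_labels.value_counts().sort_index().to_dict()


# -- validity scan -------------------------------------------------------------


def _index_triplet(X: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    return (
        float(calinski_harabasz_score(X, labels)),
        float(davies_bouldin_score(X, labels)),
        float(silhouette_score(X, labels)),
    )


def validity_scan(
    table: FeatureTable,
    ranking: ImportanceRanking,
    k_range: range = range(2, 7),
    n_init: int = 10,
    seed: int = 0,
    min_features: int = 2,
    max_features: int | None = None,
    min_votes: int = 2,
    n_null: int = 5,
    null_n_init: int = 4,
    stop_rule: str = "first_decrease",
    confidence_floor: float = 0.25,
) -> ClusterValidityReport:
    """Choose (n_features, k) by incremental k-means validity evaluation.

    At each feature-count prefix of ``ranking.rank_order`` and each k,
    the three indices are computed on the data and on ``n_null``
    column-permuted copies (which destroy the joint cluster structure but
    keep every marginal).  The working quantity is each index's gap over
    its permutation-null mean — CH and silhouette real minus null, DB
    null minus real — which makes values comparable across feature
    counts; the raw indices scale with dimension and with how stripey the
    marginals are, so comparing them directly biases the scan toward few
    features and many clusters.

    With ``stop_rule="first_decrease"`` a count is better than its
    predecessor if at least ``min_votes`` of the three gaps improve at
    their own best k, and scanning stops at the first count that is not
    better; ``"global"`` evaluates every count and takes the
    silhouette-gap maximiser.  The selected k maximises the silhouette
    gap at the selected count, ties toward smaller k.  The scan starts at
    ``min_features`` (default 2): a univariate partition is thresholding,
    not multivariate clustering, and all three indices are degenerately
    favourable in one dimension.
    """
    order = ranking.rank_order
    if not order:
        raise ContractError("ranking contains no features")
    if stop_rule not in ("first_decrease", "global"):
        raise ContractError(f"unknown stop_rule {stop_rule!r}")
    n = len(table.data)
    if min(k_range) < 2:
        raise ContractError("k_range must start at 2 or above")
    if max(k_range) >= n:
        k_range = range(min(k_range), n)
        if len(k_range) == 0:
            raise ContractError("too few participants for any k in range")
    limit = min(len(order), max_features or len(order))
    start = max(1, min(min_features, limit))
    rng = np.random.default_rng(seed)

    records = []
    best_per_count: dict[int, dict[str, float]] = {}
    sil_gap_by_count: dict[int, dict[int, float]] = {}
    selected_nf = start
    stop_reason = "all ranked features evaluated without a decrease"
    for nf in range(start, limit + 1):
        X = table.data[order[:nf]].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ContractError("missing values are not allowed in the validity scan")
        gaps_k: dict[int, tuple[float, float, float]] = {}
        for k in k_range:
            km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
            labels = km.fit_predict(X)
            ch, db, sil = _index_triplet(X, labels)
            null_ch, null_db, null_sil = [], [], []
            X_sorted = np.sort(X, axis=0)  # row-order-invariant null draws
            for _ in range(n_null):
                Xp = np.column_stack(
                    [rng.permutation(X_sorted[:, j]) for j in range(X.shape[1])]
                )
                km0 = KMeans(n_clusters=k, n_init=null_n_init, random_state=seed)
                lab0 = km0.fit_predict(Xp)
                c0, d0, s0 = _index_triplet(Xp, lab0)
                null_ch.append(c0)
                null_db.append(d0)
                null_sil.append(s0)
            g = (
                ch - float(np.mean(null_ch)),
                float(np.mean(null_db)) - db,
                sil - float(np.mean(null_sil)),
            )
            gaps_k[k] = g
            records.append(
                dict(n_features=nf, k=k, calinski_harabasz=ch, davies_bouldin=db,
                     silhouette=sil, gap_calinski_harabasz=g[0],
                     gap_davies_bouldin=g[1], gap_silhouette=g[2])
            )
        best_per_count[nf] = {
            "ch": max(v[0] for v in gaps_k.values()),
            "db": max(v[1] for v in gaps_k.values()),
            "sil": max(v[2] for v in gaps_k.values()),
        }
        sil_gap_by_count[nf] = {k: v[2] for k, v in gaps_k.items()}
        if nf == start or stop_rule == "global":
            selected_nf = nf if nf == start else selected_nf
            continue
        prev = best_per_count[nf - 1]
        cur = best_per_count[nf]
        votes = sum(int(cur[i] > prev[i]) for i in ("ch", "db", "sil"))
        if votes < min_votes:
            selected_nf = nf - 1
            stop_reason = (
                f"adding feature {nf} ({order[nf - 1]!r}) improved only "
                f"{votes}/3 null-referenced validity indices"
            )
            break
        selected_nf = nf

    if stop_rule == "global":
        selected_nf = max(
            best_per_count, key=lambda nf: max(sil_gap_by_count[nf].values())
        )
        stop_reason = "global maximum of the null-referenced silhouette"

    grid = pd.DataFrame.from_records(records)
    gaps = sil_gap_by_count[selected_nf]
    gap_best = max(gaps.values())
    selected_k = min(k for k, v in gaps.items() if v >= gap_best - 1e-12)
    return ClusterValidityReport(
        grid=grid,
        selected_n_features=selected_nf,
        selected_k=int(selected_k),
        selected_features=order[:selected_nf],
        stop_reason=stop_reason,
        confident=bool(gap_best >= confidence_floor),
    )


# -- fuzzy c-means -------------------------------------------------------------


def _fcm_once(
    X: np.ndarray, k: int, m: float, tol: float, max_iter: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[float], bool, int]:
    n = X.shape[0]
    U = rng.random((n, k))
    U /= U.sum(axis=1, keepdims=True)
    centroids = np.empty((k, X.shape[1]))
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        W = U ** m
        centroids_new = (W.T @ X) / W.sum(axis=0)[:, None]
        d2 = np.fmax(cdist(X, centroids_new, "sqeuclidean"), _D2_FLOOR)
        inv = d2 ** (-1.0 / (m - 1.0))
        U = inv / inv.sum(axis=1, keepdims=True)
        history.append(float(((U ** m) * d2).sum()))
        shift = np.abs(centroids_new - centroids).max() if it > 1 else np.inf
        centroids = centroids_new
        if shift < tol:
            converged = True
            break
    return U, centroids, history, converged, it


def fuzzy_cmeans(
    table: FeatureTable,
    feature_names: list[str],
    k: int,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 1000,
    n_restarts: int = 20,
    seed: int = 0,
) -> ClusterModel:
    """Fuzzy c-means on the named (unit-scaled) features.

    Alternates membership and centroid updates until the maximum centroid
    shift falls below ``tol``; the best of ``n_restarts`` random starts by
    final objective is kept.  Hard labels are the arg-max membership and
    cluster ids are renumbered by descending hard-cluster size (ties by
    first centroid coordinate) so repeated runs agree.
    """
    if k < 2:
        raise ContractError("k must be >= 2")
    if m <= 1:
        raise ContractError("fuzzifier m must be > 1")
    sub = table.subset_columns(feature_names)
    complete = ~sub.data.isna().any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} incomplete rows before clustering",
                      stacklevel=2)
    dat = sub.data.loc[complete]
    X = dat.to_numpy(dtype=float)
    if len(X) <= k:
        raise ContractError(f"need more than k={k} complete participants, got {len(X)}")

    if np.allclose(X, X[0], atol=1e-12):
        warnings.warn("all participants identical; memberships degenerate to 1/k",
                      stacklevel=2)

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        U, C, hist, conv, n_iter = _fcm_once(X, k, m, tol, max_iter, rng)
        if best is None or hist[-1] < best[2][-1]:
            best = (U, C, hist, conv, n_iter)
    U, C, hist, conv, n_iter = best
    if not conv:
        warnings.warn(
            f"fuzzy c-means did not converge in {max_iter} iterations "
            f"(final objective {hist[-1]:.6g})",
            stacklevel=2,
        )

    hard = U.argmax(axis=1)
    # deterministic relabelling: descending size, ties by first centroid coord
    sizes = np.bincount(hard, minlength=k)
    order = sorted(range(k), key=lambda c: (-sizes[c], C[c, 0]))
    remap = {old: new for new, old in enumerate(order)}
    U = U[:, order]
    C = C[order]
    hard = np.array([remap[h] for h in hard])

    centroids = pd.DataFrame(C, columns=feature_names,
                             index=pd.RangeIndex(k, name="cluster"))
    membership = pd.DataFrame(U, index=dat.index,
                              columns=[f"cluster_{c}" for c in range(k)])
    hard_s = pd.Series(hard, index=dat.index, name="cluster")
    return ClusterModel(
        feature_names=list(feature_names),
        fuzzifier=m,
        centroids=centroids,
        membership=membership,
        hard_labels=hard_s,
        objective=hist[-1],
        objective_history=hist,
        converged=conv,
        n_iter=n_iter,
    )


# -- metrics -------------------------------------------------------------------


def cluster_metrics(model: ClusterModel, table: FeatureTable) -> ClusterModel:
    """Fill within/between distances, silhouette and the density contrast.

    * within-cluster distance: mean Euclidean distance of hard members to
      their centroid, per cluster, on the unit scale;
    * between-cluster distance: mean pairwise centroid distance;
    * silhouette: mean silhouette over participants with hard labels
      (a singleton cluster contributes silhouette 0 for its point);
    * discrimination value: log10(mean within-cluster variance /
      between-centroid variance), a log-scaled density contrast — more
      negative means denser clusters relative to their separation.
    """
    X = table.data.loc[model.hard_labels.index, model.feature_names].to_numpy(dtype=float)
    labels = model.hard_labels.to_numpy()
    C = model.centroids.to_numpy()
    present = np.unique(labels)
    if len(present) < 2:
        raise ContractError("need at least 2 non-empty hard clusters for metrics")
    if any(np.sum(labels == c) == 1 for c in present):
        warnings.warn("singleton cluster present; its point contributes silhouette 0",
                      stacklevel=2)

    within = {}
    within_var_terms = []
    for c in present:
        pts = X[labels == c]
        dists = np.linalg.norm(pts - C[c], axis=1)
        within[int(c)] = float(dists.mean())
        within_var_terms.append((dists ** 2).mean())
    pairs = [
        np.linalg.norm(C[i] - C[j])
        for i in range(model.k)
        for j in range(i + 1, model.k)
    ]
    model.within_cluster_distances = within
    model.between_cluster_distance = float(np.mean(pairs))
    model.silhouette_index = float(silhouette_score(X, labels))
    grand = C.mean(axis=0)
    between_var = float(((C - grand) ** 2).sum(axis=1).mean())
    within_var = float(np.mean(within_var_terms))
    with np.errstate(divide="ignore"):
        model.discrimination_value = float(np.log10(within_var / between_var)) \
            if between_var > 0 and within_var > 0 else -np.inf
    return model
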