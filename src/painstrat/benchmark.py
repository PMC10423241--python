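"""Repeated-holdout benchmarking of sub-group classifiability.

Four standard multi-class classifiers (RBF-kernel SVM with one-vs-one
decision, Gaussian naive Bayes, k-nearest-neighbour, random forest) are
trained on the same stratified 80/20 splits over a configurable number of
runs (default 30) and scored by test-set misclassification rate.  With a
minority sub-group of only a few participants, stratification is what
keeps each test set populated by every class.  The per-classifier mean
error carries a t-based 95% confidence interval across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .data import FeatureTable
from .errors import ContractError, DomainError

CLASSIFIERS = ("svm", "naive_bayes", "knn", "random_forest")


def _make_classifiers(seed: int) -> dict[str, object]:
    return {
        "svm": SVC(kernel="rbf", C=1.0, decision_function_shape="ovo",
                   random_state=seed),
        "naive_bayes": GaussianNB(),
        "knn": KNeighborsClassifier(n_neighbors=5, metric="euclidean"),
        "random_forest": RandomForestClassifier(n_estimators=500, random_state=seed),
    }


@dataclass
class ClassificationReport:
    errors: pd.DataFrame  # runs x classifiers, error rate in [0, 1]
    setting: str  # "cases_only" or "cases_plus_controls"
    seed: int
    test_fraction: float

    @property
    def mean_error(self) -> pd.Series:
        return self.errors.mean()

    def ci95(self, classifier: str) -> tuple[float, float, float]:
        return error_ci(self.errors[classifier].to_numpy(), level=0.95)

    def summary(self) -> pd.DataFrame:
        rows = {}
        for clf in self.errors.columns:
            mean, lo, hi = self.ci95(clf)
            rows[clf] = dict(mean_error=mean, ci_low=lo, ci_high=hi)
        out = pd.DataFrame.from_dict(rows, orient="index")
        out.index.name = "classifier"
        return out


def error_ci(errors, level: float = 0.95) -> tuple[float, float, float]:
    """Mean error with a t-interval across runs, truncated to [0, 1]."""
    e = np.asarray(errors, dtype=float)
    if e.size < 2:
        raise ContractError("need at least 2 error values for an interval")
    if not 0 < level < 1:
        raise ContractError("level must be in (0, 1)")
    if np.any((e < 0) | (e > 1)):
        raise DomainError("error rates must lie in [0, 1]")
    mean = float(e.mean())
    sem = float(e.std(ddof=1) / np.sqrt(e.size))
    t = float(stats.t.ppf(0.5 + level / 2, df=e.size - 1))
    return mean, max(0.0, mean - t * sem), min(1.0, mean + t * sem)


def holdout_benchmark(
    table: FeatureTable,
    labels: pd.Series,
    n_runs: int = 30,
    test_fraction: float = 0.2,
    seed: int = 0,
    setting: str = "cases_only",
    feature_names: list[str] | None = None,
) -> ClassificationReport:
    """Repeated stratified holdout across the four classifiers.

    Every run re-splits with a run-specific seed derived from the master
    seed; all four classifiers see the identical split.  ``labels`` may be
    sub-group ids (cases only) or sub-groups plus a control class.
    """
    if not 0 < test_fraction <= 0.5:
        raise ContractError("test_fraction must be in (0, 0.5]")
    names = feature_names or table.variables
    dat = table.data.loc[labels.index, names]
    complete = ~dat.isna().any(axis=1)
    dat, labels = dat.loc[complete], labels.loc[complete]
    X = dat.to_numpy(dtype=float)
    y = labels.astype(str).to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ContractError("need at least 2 classes")
    for cls, cnt in zip(classes, counts):
        if cnt < 2:
            raise ContractError(f"class {cls!r} has only {cnt} member(s)")

    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    errors = np.empty((n_runs, len(CLASSIFIERS)))
    for r, run_seed in enumerate(run_seeds):
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=test_fraction, stratify=y, random_state=int(run_seed)
        )
        for c, name in enumerate(CLASSIFIERS):
            clf = _make_classifiers(int(run_seed))[name]
            clf.fit(X_tr, y_tr)
            errors[r, c] = float(np.mean(clf.predict(X_te) != y_te))
    frame = pd.DataFrame(errors, columns=list(CLASSIFIERS))
    frame.index.name = "run"
    return ClassificationReport(
        errors=frame, setting=setting, seed=seed, test_fraction=test_fraction
    )
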