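"""Univariate case/control screening and multicollinearity filtering.

Per-variable two-sample t-tests (Welch by default) pick candidate
variables at an unadjusted alpha; Benjamini-Hochberg q-values are reported
alongside for context but do not gate selection, matching a pilot-study
screening posture.  A Pearson-correlation filter then drops one member of
every pair exceeding an |r| threshold, with a deterministic tie rule, so
no near-duplicate variables enter the downstream unsupervised steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import CASE, CONTROL, FeatureTable
from .errors import ContractError, DomainError


@dataclass
class ScreeningResult:
    """Outputs of the screening stage."""

    stats: pd.DataFrame  # index: variable; columns: t, p, q, selected, untestable
    alpha: float
    collinearity_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    removed: dict[str, str] = field(default_factory=dict)  # variable -> reason

    @property
    def selected(self) -> list[str]:
        sel = self.stats.index[self.stats["selected"]]
        return [v for v in sel if v not in self.removed]

    @property
    def n_selected_unadjusted(self) -> int:
        return int(self.stats["selected"].sum())

    @property
    def n_selected_fdr(self) -> int:
        return int((self.stats["q"] < self.alpha).sum())


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} min(1, m * p_(j) / j) over the ascending order
    statistics; monotone non-decreasing in p-rank and always >= p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def group_t_tests(
    table: FeatureTable, alpha: float = 0.05, equal_var: bool = False
) -> ScreeningResult:
    """Two-sample t-test of case vs control for every variable.

    Selection is by unadjusted p < alpha; q-values (BH) are attached.  A
    variable with fewer than two non-missing observations in either group
    is marked untestable and never selected.
    """
    if not 0 < alpha < 1:
        raise ContractError("alpha must be in (0, 1)")
    case_mask = (table.group == CASE).to_numpy()
    ctrl_mask = (table.group == CONTROL).to_numpy()
    if case_mask.sum() == 0 or ctrl_mask.sum() == 0:
        raise ContractError("both case and control groups must be present")

    rows = {}
    for name in table.variables:
        col = table.data[name].to_numpy(dtype=float)
        a = col[case_mask]
        b = col[ctrl_mask]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.size < 2 or b.size < 2:
            rows[name] = (np.nan, np.nan, False, True)
            continue
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        if not np.isfinite(p):  # e.g. zero variance in both groups
            rows[name] = (np.nan, np.nan, False, True)
            continue
        rows[name] = (float(t), float(p), bool(p < alpha), False)

    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["t", "p", "selected", "untestable"]
    )
    out.index.name = "variable"
    testable = ~out["untestable"]
    q = np.full(len(out), np.nan)
    if testable.any():
        q[testable.to_numpy()] = bh_fdr(out.loc[testable, "p"].to_numpy())
    out.insert(2, "q", q)
    return ScreeningResult(stats=out, alpha=alpha)


def collinearity_filter(
    table: FeatureTable,
    result: ScreeningResult,
    candidates: list[str] | None = None,
    r_threshold: float = 0.8,
) -> ScreeningResult:
    """Drop one member of every candidate pair with |r| > threshold.

    Pearson correlations use pairwise-complete observations.  Tie rule:
    the member with the larger univariate p-value is dropped; at equal p
    the later column goes.  Zero-variance candidates are excluded with a
    reason.  The result object is updated in place and returned.
    """
    if not 0 < r_threshold < 1:
        raise ContractError("r_threshold must be in (0, 1)")
    if candidates is None:
        candidates = [v for v in table.variables if v in result.selected]
    unknown = [c for c in candidates if c not in table.variables]
    if unknown:
        raise ContractError(f"candidates not in table: {unknown}")

    live = []
    for name in candidates:
        col = table.data[name].dropna()
        if col.nunique() <= 1:
            result.removed[name] = "zero variance among complete observations"
        else:
            live.append(name)

    corr = table.data[live].corr(method="pearson", min_periods=2)
    p_of = result.stats["p"]
    order = {name: i for i, name in enumerate(table.variables)}
    # examine pairs in column order for determinism
    for i, a in enumerate(live):
        if a in result.removed:
            continue
        for b in live[i + 1:]:
            if b in result.removed or a in result.removed:
                continue
            r = corr.loc[a, b]
            if pd.isna(r) or abs(r) <= r_threshold:
                continue
            result.collinearity_pairs.append((a, b, float(r)))
            pa, pb = p_of.get(a, np.nan), p_of.get(b, np.nan)
            if np.isnan(pa) and np.isnan(pb):
                drop = b if order[a] <= order[b] else a
            elif np.isnan(pb) or (not np.isnan(pa) and pa > pb):
                drop = a
            elif np.isnan(pa) or pb > pa:
                drop = b
            else:  # equal p: drop the later column
                drop = b if order[a] <= order[b] else a
            keep = a if drop == b else b
            result.removed[drop] = (
                f"|r| = {abs(r):.3f} > {r_threshold} with {keep!r}"
            )
    return result


def force_remove(result: ScreeningResult, variables: list[str]) -> ScreeningResult:
    """Record analyst-specified removals (e.g. a variable judged redundant
    with a retained near-duplicate) so the handoff to ranking is explicit."""
    for v in variables:
        if v in result.stats.index and v not in result.removed:
            result.removed[v] = "removed by configuration (force_remove)"
    return result
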