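"""Post-hoc characterisation of derived sub-groups.

One-way ANOVA with Tukey-HSD-adjusted pairwise comparisons describes each
variable across controls and sub-groups; Pearson correlations with
Fisher-z confidence intervals relate the cluster-driving variables to pain
intensity and disability within cases; chi-square tests handle categorical
contrasts such as sex by group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ContractError, DomainError


@dataclass
class GroupComparisonTable:
    """Per-variable group summaries, ANOVA and Tukey pairwise p-values."""

    summaries: pd.DataFrame  # variable x (group, stat) means/SDs
    anova: pd.DataFrame  # variable -> F, p, flagged
    tukey: pd.DataFrame  # rows: variable, group_a, group_b, meandiff, p_adj
    flagged: dict[str, str] = field(default_factory=dict)


def anova_tukey(
    data: pd.DataFrame, group_labels: pd.Series, variables: list[str] | None = None
) -> GroupComparisonTable:
    """One-way ANOVA + Tukey HSD for every variable across groups.

    Groups must number at least two with at least two members each.
    Constant variables are flagged and excluded from testing, not fatal.
    With exactly two groups the ANOVA p equals the pooled-variance
    two-sample t-test p, and Tukey reduces to the same comparison.
    """
    variables = variables if variables is not None else list(data.columns)
    labels = group_labels.loc[data.index]
    groups = labels.dropna().unique().tolist()
    if len(groups) < 2:
        raise ContractError("need at least 2 groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ContractError(f"group {g!r} has fewer than 2 members")

    summary_rows, anova_rows, tukey_rows, flagged = [], [], [], {}
    for var in variables:
        col = data[var]
        complete = col.notna() & labels.notna()
        x, lab = col[complete].astype(float), labels[complete]
        for g in groups:
            vals = x[lab == g]
            summary_rows.append(
                dict(variable=var, group=g, n=len(vals),
                     mean=float(vals.mean()) if len(vals) else np.nan,
                     sd=float(vals.std(ddof=1)) if len(vals) > 1 else np.nan)
            )
        if x.nunique() <= 1:
            flagged[var] = "constant across all groups"
            anova_rows.append(dict(variable=var, F=np.nan, p=np.nan))
            continue
        samples = [x[lab == g].to_numpy() for g in groups]
        F, p = stats.f_oneway(*samples)
        anova_rows.append(dict(variable=var, F=float(F), p=float(p)))
        res = pairwise_tukeyhsd(x.to_numpy(), lab.to_numpy())
        frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
        for _, row in frame.iterrows():
            tukey_rows.append(
                dict(variable=var, group_a=str(row["group1"]),
                     group_b=str(row["group2"]), meandiff=float(row["meandiff"]),
                     p_adj=float(row["p-adj"]))
            )

    return GroupComparisonTable(
        summaries=pd.DataFrame(summary_rows),
        anova=pd.DataFrame(anova_rows).set_index("variable"),
        tukey=pd.DataFrame(tukey_rows),
        flagged=flagged,
    )


def pearson_ci(x, y, level: float = 0.95) -> tuple[float, float, float, float]:
    """Pearson r with a Fisher-z confidence interval and two-sided p.

    Returns (r, low, high, p) over complete pairs; requires at least four.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ContractError("need at least 4 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DomainError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, r, r, float(p)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(x.size - 3)
    zcrit = stats.norm.ppf(0.5 + level / 2)
    return r, float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se)), float(p)


def chi_square_table(contingency, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square statistic and p for a counts matrix.

    Continuity correction is off by default (the group-comparison tables
    here are mostly larger than 2x2); enable via ``correction``.
    """
    obs = np.asarray(contingency, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ContractError("contingency table must be at least 2x2")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise DomainError("contingency entries must be non-negative integers")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ContractError("contingency table has an all-zero row or column")
    res = stats.chi2_contingency(obs, correction=correction)
    return float(res.statistic), float(res.pvalue)
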