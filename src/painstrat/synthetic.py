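"""Synthetic chronic low back pain cohort generator.

Emulates the study design the pipeline targets: 21 pain-free controls and
21 cases, the cases split into two latent sub-groups (n = 16 with
near-control psychosocial scores, n = 5 with markedly worse scores).  The
default configuration carries the published group means and standard
deviations for the ten variables that separate the groups (four PROMIS
psychosocial scores, central sensitisation inventory, satisfaction in
social roles, maximal extension strength, lumbar pressure-pain threshold,
lumbar disc T2 and 12-month pain-site count), plus non-discriminating
nuisance variables in each domain that any screening step should reject.

Values are drawn per group from a multivariate normal, clipped to each
variable's declared scale (with a warning if clipping is material), and
discrete count variables are rounded.  The hidden sub-group labels are
returned separately so recovery can be scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CASE, CONTROL, Domain, FeatureTable, VariableMeta
from .errors import ConfigurationError

CONTROL_LABEL = "control"
SUB1 = "sub1"
SUB2 = "sub2"

# name -> (domain, scale_min, scale_max, higher_is_better, discrete,
#          (control mean, sd), (sub1 mean, sd), (sub2 mean, sd))
_STUDY_VARIABLES = {
    "cognitive_function": (
        Domain.PSYCHOSOCIAL, 8, 40, True, False, (36.2, 4.4), (35.8, 4.1), (19.8, 2.5)),
    "depressive_symptoms": (
        Domain.PSYCHOSOCIAL, 8, 40, False, False, (8.8, 1.3), (9.4, 1.8), (20.6, 6.9)),
    "general_self_efficacy": (
        Domain.PSYCHOSOCIAL, 10, 50, True, False, (44.1, 5.4), (43.1, 4.0), (27.2, 6.6)),
    "anxiety_symptoms": (
        Domain.PSYCHOSOCIAL, 8, 40, False, False, (11.5, 4.4), (12.6, 4.8), (24.8, 5.5)),
    "satisfaction_social_roles": (
        Domain.PSYCHOSOCIAL, 8, 40, True, False, (38.0, 3.8), (34.8, 7.7), (24.8, 7.4)),
    "central_sensitisation": (
        Domain.NERVOUS, 0, 100, False, False, (17.1, 10.3), (32.3, 11.8), (51.2, 11.1)),
    "lumbar_ppt": (
        Domain.NERVOUS, 0, 11.3, True, False, (9.1, 2.2), (7.6, 2.7), (6.7, 2.4)),
    "max_extension_strength": (
        Domain.SPINAL, 0, 150, True, False, (68.7, 16.2), (53.7, 21.8), (49.2, 17.9)),
    "lumbar_t2": (
        Domain.SPINAL, 40, 180, True, False, (103.4, 13.5), (95.1, 9.9), (96.9, 15.7)),
    "pain_sites_12mo": (
        Domain.OTHER, 0, 10, False, True, (1.4, 1.4), (5.2, 2.5), (6.6, 1.9)),
}

_NUISANCE_DOMAINS = (Domain.PSYCHOSOCIAL, Domain.SPINAL, Domain.NERVOUS)


@dataclass(frozen=True)
class GroupSpec:
    """One latent group: label, size, and a mean/SD per variable."""

    label: str
    n: int
    means: dict[str, float]
    sds: dict[str, float]

    def __post_init__(self):
        if self.n < 1:
            raise ConfigurationError(f"group {self.label!r}: n must be >= 1")
        if any(s < 0 for s in self.sds.values()):
            raise ConfigurationError(f"group {self.label!r}: negative SD")


@dataclass
class SyntheticConfig:
    """Full recipe for one synthetic cohort draw."""

    groups: list[GroupSpec]
    variables: list[VariableMeta]
    discrete: set[str] = field(default_factory=set)
    # within-group correlations between named variable pairs, each in (-1, 1)
    correlations: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0
    clip_warn_fraction: float = 0.05

    def __post_init__(self):
        names = [m.name for m in self.variables]
        for g in self.groups:
            missing = [v for v in names if v not in g.means or v not in g.sds]
            if missing:
                raise ConfigurationError(
                    f"group {g.label!r} lacks mean/SD for {missing}"
                )

    def correlation_matrix(self) -> np.ndarray:
        names = [m.name for m in self.variables]
        idx = {n: i for i, n in enumerate(names)}
        corr = np.eye(len(names))
        for (a, b), rho in self.correlations.items():
            if not -1 < rho < 1:
                raise ConfigurationError(f"correlation for ({a}, {b}) outside (-1, 1)")
            corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
        return corr


def default_config(
    n_nuisance: int = 10,
    correlations: dict[tuple[str, str], float] | None = None,
    seed: int = 0,
) -> SyntheticConfig:
    """The published-study configuration: groups 21/16/5 with the printed
    means and SDs, plus ``n_nuisance`` no-signal variables per domain
    (mean 0.5, SD 0.15 on a 0-1 scale, identical across groups)."""
    variables: list[VariableMeta] = []
    means: dict[str, dict[str, float]] = {CONTROL_LABEL: {}, SUB1: {}, SUB2: {}}
    sds: dict[str, dict[str, float]] = {CONTROL_LABEL: {}, SUB1: {}, SUB2: {}}
    discrete: set[str] = set()
    for name, (dom, lo, hi, hib, disc, ctrl, s1, s2) in _STUDY_VARIABLES.items():
        variables.append(VariableMeta(name, dom, lo, hi, hib))
        if disc:
            discrete.add(name)
        for label, (mu, sd) in zip((CONTROL_LABEL, SUB1, SUB2), (ctrl, s1, s2)):
            means[label][name] = mu
            sds[label][name] = sd
    for dom in _NUISANCE_DOMAINS:
        for i in range(n_nuisance):
            name = f"nuisance_{dom.value}_{i + 1:02d}"
            variables.append(VariableMeta(name, dom, 0.0, 1.0, False))
            for label in (CONTROL_LABEL, SUB1, SUB2):
                means[label][name] = 0.5
                sds[label][name] = 0.15
    groups = [
        GroupSpec(CONTROL_LABEL, 21, means[CONTROL_LABEL], sds[CONTROL_LABEL]),
        GroupSpec(SUB1, 16, means[SUB1], sds[SUB1]),
        GroupSpec(SUB2, 5, means[SUB2], sds[SUB2]),
    ]
    return SyntheticConfig(
        groups=groups,
        variables=variables,
        discrete=discrete,
        correlations=dict(correlations or {}),
        seed=seed,
    )


def generate_cohort(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[FeatureTable, pd.Series]:
    """Draw one cohort.

    Returns the feature table with ``group`` collapsed to case/control and
    a separate series of hidden latent labels (control/sub1/sub2).  The
    same seed always produces the identical table.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    names = [m.name for m in config.variables]
    corr = config.correlation_matrix()
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError("correlation matrix is not positive definite") from exc

    rows, latent, ids = [], [], []
    counter = 0
    n_clipped = 0
    n_cells = 0
    for g in config.groups:
        mu = np.array([g.means[v] for v in names])
        sd = np.array([g.sds[v] for v in names])
        z = rng.standard_normal((g.n, len(names))) @ chol.T
        draws = mu + sd * z
        for m_i, meta in enumerate(config.variables):
            col = draws[:, m_i]
            clipped = np.clip(col, meta.scale_min, meta.scale_max)
            n_clipped += int(np.sum(clipped != col))
            n_cells += g.n
            if meta.name in config.discrete:
                clipped = np.round(clipped)
            draws[:, m_i] = clipped
        rows.append(draws)
        latent.extend([g.label] * g.n)
        for _ in range(g.n):
            counter += 1
            ids.append(f"P{counter:03d}")

    if n_cells and n_clipped / n_cells > config.clip_warn_fraction:
        warnings.warn(
            f"{n_clipped / n_cells:.1%} of draws clipped at scale bounds",
            stacklevel=2,
        )
    index = pd.Index(ids, name="participant_id")
    data = pd.DataFrame(np.vstack(rows), index=index, columns=names)
    latent_s = pd.Series(latent, index=index, name="latent_group")
    group = latent_s.map(lambda g: CONTROL if g == CONTROL_LABEL else CASE)
    group.name = "group"
    table = FeatureTable(data=data, group=group, meta=list(config.variables))
    return table, latent_s
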