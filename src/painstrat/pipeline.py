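"""End-to-end orchestration of the sub-grouping pipeline.

Order of stages: (1) univariate screening with FDR context and a
collinearity filter; (2) unit-interval normalisation and random-forest
case/control feature weighting; (3) Laplacian-score ranking within cases;
(4) incremental cluster-validity scan; (5) fuzzy c-means sub-grouping with
quality metrics; (6) repeated-holdout classifier benchmark, with and
without controls; (7) post-hoc ANOVA/Tukey group characterisation and
correlations with pain/disability outcomes.  Sub-domain analyses rerun
stages 3-6 within one biopsychosocial domain at a time, and the resulting
per-domain labels are combined into one profile per participant.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .benchmark import ClassificationReport, holdout_benchmark
from .clustering import (
    ClusterModel,
    ClusterValidityReport,
    cluster_metrics,
    fuzzy_cmeans,
    validity_scan,
)
from .data import (
    CONTROL,
    Domain,
    FeatureTable,
    NormalisedTable,
    normalise_01,
)
from .errors import ContractError, DomainError
from .posthoc import GroupComparisonTable, anova_tukey, pearson_ci
from .ranking import ImportanceRanking, laplacian_rank, rf_feature_weighting
from .screening import (
    ScreeningResult,
    collinearity_filter,
    force_remove,
    group_t_tests,
)

NORMAL_LABEL = "normal"


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, every one seed-pinned or deterministic."""

    alpha: float = 0.05
    r_threshold: float = 0.8
    equal_var: bool = False  # False = Welch t-tests
    force_remove: list[str] = field(default_factory=list)
    # ranking
    k_neighbours: int = 5
    bandwidth: float | None = None  # None = mean pairwise squared distance
    rf_n_estimators: int = 500
    rf_permutation_repeats: int = 50
    run_rf_weighting: bool = True
    # clustering
    k_min: int = 2
    k_max: int = 6
    fuzzifier: float = 2.0
    tol: float = 1e-5
    max_iter: int = 1000
    n_restarts: int = 20
    # classification
    n_runs: int = 30
    test_fraction: float = 0.2
    # post-hoc
    outcome_variables: list[str] = field(default_factory=list)
    # labelling: minimum centroid deviation (unit scale) to name a feature
    deviation_threshold: float = 0.15
    seed: int = 0

    @property
    def k_range(self) -> range:
        return range(self.k_min, self.k_max + 1)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SubDomainProfile:
    """Per-participant combination of the three sub-domain labels."""

    participant_id: str
    psychosocial_label: str
    spinal_label: str
    nervous_label: str
    combined_label: str
    domains_contributing: list[str]


@dataclass
class SubdomainResult:
    domain: str
    skipped: bool
    reason: str = ""
    variables: list[str] = field(default_factory=list)
    ranking: ImportanceRanking | None = None
    validity: ClusterValidityReport | None = None
    model: ClusterModel | None = None
    labels: pd.Series | None = None  # participant -> text label
    benchmark: ClassificationReport | None = None


@dataclass
class PipelineResult:
    screening: ScreeningResult
    normalised: NormalisedTable
    rf_ranking: ImportanceRanking | None
    laplacian_ranking: ImportanceRanking
    validity: ClusterValidityReport
    model: ClusterModel
    cluster_names: dict[int, str]
    benchmark_cases: ClassificationReport
    benchmark_with_controls: ClassificationReport
    comparisons: GroupComparisonTable
    correlations: pd.DataFrame
    manifest: dict

    @property
    def subgroup_labels(self) -> pd.Series:
        """Case labels 'sub1', 'sub2', ... ordered by descending cluster size."""
        return self.model.hard_labels.map(lambda c: f"sub{c + 1}")


def _hash_table(table: FeatureTable) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(table.data, index=True).to_numpy().tobytes())
    h.update(",".join(table.group.astype(str)).encode())
    return h.hexdigest()[:16]


def name_clusters(
    model: ClusterModel,
    normalised: NormalisedTable,
    deviation_threshold: float = 0.15,
) -> dict[int, str]:
    """Name clusters relative to the control profile.

    The cluster whose centroid is nearest to the control means (on the
    clustering features, unit scale) is labelled ``"normal"``; every other
    cluster is named by its deviating features with a high/low direction,
    e.g. ``"high depressive_symptoms, low general_self_efficacy"``.
    """
    controls = normalised.controls()
    if len(controls.data) == 0:
        raise ContractError("no controls available to anchor cluster naming")
    ctrl_mean = controls.data[model.feature_names].mean().to_numpy()
    C = model.centroids.to_numpy()
    dists = np.linalg.norm(C - ctrl_mean, axis=1)
    normal_cluster = int(np.argmin(dists))
    names = {}
    for c in range(model.k):
        if c == normal_cluster:
            names[c] = NORMAL_LABEL
            continue
        parts = []
        for j, feat in enumerate(model.feature_names):
            delta = C[c, j] - ctrl_mean[j]
            if abs(delta) >= deviation_threshold:
                parts.append(f"{'high' if delta > 0 else 'low'} {feat}")
        names[c] = ", ".join(parts) if parts else f"atypical (cluster {c})"
    return names


def run_pipeline(
    table: FeatureTable, config: PipelineConfig | None = None
) -> PipelineResult:
    """Execute the full primary analysis on one cohort table."""
    config = config or PipelineConfig()

    # 1 - screening: t-tests, FDR context, collinearity, forced removals
    screening = group_t_tests(table, alpha=config.alpha, equal_var=config.equal_var)
    collinearity_filter(table, screening, r_threshold=config.r_threshold)
    force_remove(screening, config.force_remove)
    candidates = screening.selected
    if len(candidates) < 2:
        raise ContractError(
            f"screening left {len(candidates)} candidate variable(s); "
            "need at least 2 to cluster"
        )

    # 2 - normalise (all participants as reference) and RF weighting
    normalised = normalise_01(table)
    rf_ranking = None
    if config.run_rf_weighting:
        rf_ranking = rf_feature_weighting(
            normalised,
            n_estimators=config.rf_n_estimators,
            n_permutation_repeats=config.rf_permutation_repeats,
            seed=config.seed,
        )

    # 3 - Laplacian ranking within cases on the surviving candidates
    cases = normalised.cases()
    lap = laplacian_rank(
        cases,
        k_neighbours=config.k_neighbours,
        bandwidth=config.bandwidth,
        candidates=candidates,
    )

    # 4 - validity scan over ranked prefixes
    validity = validity_scan(
        cases.subset_columns(lap.rank_order),
        lap,
        k_range=config.k_range,
        seed=config.seed,
    )

    # 5 - fuzzy c-means + metrics
    model = fuzzy_cmeans(
        cases,
        validity.selected_features,
        k=validity.selected_k,
        m=config.fuzzifier,
        tol=config.tol,
        max_iter=config.max_iter,
        n_restarts=config.n_restarts,
        seed=config.seed,
    )
    cluster_metrics(model, cases)
    cluster_names = name_clusters(model, normalised, config.deviation_threshold)

    # 6 - classifier benchmark, cases only and with controls
    sub_labels = model.hard_labels.map(lambda c: f"sub{c + 1}")
    bench_cases = holdout_benchmark(
        cases,
        sub_labels,
        n_runs=config.n_runs,
        test_fraction=config.test_fraction,
        seed=config.seed,
        setting="cases_only",
        feature_names=validity.selected_features,
    )
    all_labels = pd.concat(
        [sub_labels, pd.Series(CONTROL, index=normalised.controls().data.index)]
    ).reindex(normalised.data.index)
    bench_all = holdout_benchmark(
        normalised,
        all_labels.dropna(),
        n_runs=config.n_runs,
        test_fraction=config.test_fraction,
        seed=config.seed,
        setting="cases_plus_controls",
        feature_names=validity.selected_features,
    )

    # 7 - post-hoc: ANOVA/Tukey on the raw scale; correlations within cases
    group3 = all_labels.dropna()
    comparisons = anova_tukey(
        table.data.loc[group3.index], group3, variables=validity.selected_features
    )
    corr_rows = []
    for outcome in config.outcome_variables:
        if outcome not in table.variables:
            continue
        for feat in validity.selected_features:
            case_ids = model.hard_labels.index
            try:
                r, lo, hi, p = pearson_ci(
                    table.data.loc[case_ids, feat], table.data.loc[case_ids, outcome]
                )
            except (ContractError, DomainError) as exc:  # degenerate outcome column
                warnings.warn(f"correlation {feat} ~ {outcome} skipped: {exc}",
                              stacklevel=2)
                continue
            corr_rows.append(
                dict(feature=feat, outcome=outcome, r=r, ci_low=lo, ci_high=hi, p=p)
            )
    correlations = pd.DataFrame(
        corr_rows, columns=["feature", "outcome", "r", "ci_low", "ci_high", "p"]
    )

    manifest = dict(
        seed=config.seed,
        config=config.to_dict(),
        input_hash=_hash_table(table),
        n_participants=len(table.data),
        n_cases=table.n_cases,
        n_controls=table.n_controls,
        n_variables=len(table.variables),
        n_selected_unadjusted=screening.n_selected_unadjusted,
        n_selected_fdr=screening.n_selected_fdr,
        candidates=candidates,
        selected_features=validity.selected_features,
        selected_k=validity.selected_k,
        cluster_sizes={str(k): v for k, v in model.cluster_sizes.items()},
        silhouette=model.silhouette_index,
        between_cluster_distance=model.between_cluster_distance,
        within_cluster_distances={
            str(k): v for k, v in model.within_cluster_distances.items()
        },
        discrimination_value=model.discrimination_value,
        mean_error_cases=bench_cases.mean_error.to_dict(),
        mean_error_with_controls=bench_all.mean_error.to_dict(),
    )
    return PipelineResult(
        screening=screening,
        normalised=normalised,
        rf_ranking=rf_ranking,
        laplacian_ranking=lap,
        validity=validity,
        model=model,
        cluster_names=cluster_names,
        benchmark_cases=bench_cases,
        benchmark_with_controls=bench_all,
        comparisons=comparisons,
        correlations=correlations,
        manifest=manifest,
    )


def run_subdomain(
    table: FeatureTable,
    config: PipelineConfig,
    domain: Domain | str,
    survivors: list[str],
) -> SubdomainResult:
    """Rerun ranking -> scan -> clustering -> benchmark within one domain.

    ``survivors`` are the variables that passed the primary screening; the
    sub-domain analysis uses those belonging to the requested domain.  A
    domain with fewer than two surviving variables is skipped with a
    reason rather than an error.
    """
    domain = Domain(domain)
    domain_vars = [
        v for v in survivors if table.meta_for(v).domain == domain
    ]
    if len(domain_vars) < 2:
        return SubdomainResult(
            domain=domain.value,
            skipped=True,
            reason=(
                f"only {len(domain_vars)} surviving variable(s) in domain "
                f"{domain.value!r}; need at least 2"
            ),
            variables=domain_vars,
        )
    normalised = normalise_01(table)
    cases = normalised.cases()
    lap = laplacian_rank(
        cases,
        k_neighbours=config.k_neighbours,
        bandwidth=config.bandwidth,
        candidates=domain_vars,
    )
    validity = validity_scan(
        cases.subset_columns(lap.rank_order), lap, k_range=config.k_range,
        seed=config.seed,
    )
    model = fuzzy_cmeans(
        cases,
        validity.selected_features,
        k=validity.selected_k,
        m=config.fuzzifier,
        tol=config.tol,
        max_iter=config.max_iter,
        n_restarts=config.n_restarts,
        seed=config.seed,
    )
    cluster_metrics(model, cases)
    names = name_clusters(model, normalised, config.deviation_threshold)
    labels = model.hard_labels.map(names)
    labels.name = f"{domain.value}_label"
    try:
        bench = holdout_benchmark(
            cases,
            model.hard_labels.map(lambda c: f"sub{c + 1}"),
            n_runs=config.n_runs,
            test_fraction=config.test_fraction,
            seed=config.seed,
            setting="cases_only",
            feature_names=validity.selected_features,
        )
    except (ContractError, ValueError) as exc:
        # many small clusters can make a stratified holdout infeasible
        warnings.warn(f"{domain.value}: benchmark skipped ({exc})", stacklevel=2)
        bench = None
    return SubdomainResult(
        domain=domain.value,
        skipped=False,
        variables=domain_vars,
        ranking=lap,
        validity=validity,
        model=model,
        labels=labels,
        benchmark=bench,
    )


_DOMAIN_ORDER = ("psychosocial", "spinal", "nervous")


def combine_subdomain_labels(
    labels_by_domain: dict[str, pd.Series]
) -> list[SubDomainProfile]:
    """Combine per-domain labels into one overall profile per participant.

    The combined label concatenates the non-"normal" domain labels in the
    fixed order psychosocial -> spinal -> nervous; participants normal in
    all three domains get an empty combined label.  Every participant must
    carry a label in every domain.
    """
    missing = [d for d in _DOMAIN_ORDER if d not in labels_by_domain]
    if missing:
        raise ContractError(f"missing domain label series: {missing}")
    index = labels_by_domain[_DOMAIN_ORDER[0]].index
    for d in _DOMAIN_ORDER:
        s = labels_by_domain[d]
        if set(s.index) != set(index) or s.isna().any():
            raise ContractError(f"participants missing a {d!r} label")
    profiles = []
    for pid in index:
        labels = {d: str(labels_by_domain[d].loc[pid]) for d in _DOMAIN_ORDER}
        contributing = [
            d for d in _DOMAIN_ORDER if not labels[d].startswith(NORMAL_LABEL)
        ]
        combined = "; ".join(labels[d] for d in contributing)
        profiles.append(
            SubDomainProfile(
                participant_id=str(pid),
                psychosocial_label=labels["psychosocial"],
                spinal_label=labels["spinal"],
                nervous_label=labels["nervous"],
                combined_label=combined,
                domains_contributing=contributing,
            )
        )
    return profiles


def save_manifest(result: PipelineResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.manifest, indent=2, default=str) + "\n")
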