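import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans

from painstrat.clustering import (
    cluster_metrics,
    fuzzy_cmeans,
    validity_scan,
)
from painstrat.errors import ContractError
from painstrat.ranking import ImportanceRanking, RankMethod
from .conftest import make_table


def blob_table(seed=0, n=30, gap=0.45, sd=0.12, n_noise=6):
    """Two Gaussian blobs in 2 informative features + appended noise."""
    rng = np.random.default_rng(seed)
    lab = rng.permutation(np.array([0] * (n // 2) + [1] * (n - n // 2)))
    cols = {
        "f1": lab * gap + rng.normal(0, sd, n),
        "f2": lab * gap + rng.normal(0, sd, n),
    }
    for i in range(n_noise):
        cols[f"noise{i}"] = rng.random(n) * 0.8
    table = make_table(cols, ["case"] * n, scale=(-5, 5))
    ranking = ImportanceRanking(
        RankMethod.LAPLACIAN,
        pd.Series(np.arange(len(cols), dtype=float), index=list(cols)),
        list(cols),
    )
    return table, ranking, lab


class TestFuzzyCMeans:
    def test_two_point_split_is_crisp(self):
        table = make_table({"x": [0.0, 1.0, 0.05, 0.95], "y": [0.0, 1.0, 0.0, 1.0]},
                           ["case"] * 4, scale=(0, 1))
        model = fuzzy_cmeans(table, ["x", "y"], k=2, seed=0)
        U = model.membership.to_numpy()
        assert U.max(axis=1).min() > 0.95
        assert sorted(model.cluster_sizes.values()) == [2, 2]

    def test_identical_points_degenerate_to_uniform(self):
        table = make_table({"x": [0.5] * 6, "y": [0.5] * 6}, ["case"] * 6,
                           scale=(0, 1))
        with pytest.warns(UserWarning, match="identical"):
            model = fuzzy_cmeans(table, ["x", "y"], k=2, seed=0)
        np.testing.assert_allclose(model.membership.to_numpy(), 0.5, atol=1e-6)

    def test_memberships_normalised_and_objective_monotone(self, cases_normalised):
        cases, _ = cases_normalised
        model = fuzzy_cmeans(
            cases, ["cognitive_function", "depressive_symptoms"], k=2, seed=4
        )
        U = model.membership.to_numpy()
        np.testing.assert_allclose(U.sum(axis=1), 1.0, atol=1e-6)
        assert U.min() >= 0.0 and U.max() <= 1.0
        hist = np.array(model.objective_history)
        assert np.all(np.diff(hist) <= 1e-9)
        assert (model.hard_labels == U.argmax(axis=1)).all()

    def test_near_crisp_fuzzifier_recovers_kmeans_partition(self):
        table, _, lab = blob_table(seed=2, n_noise=0)
        model = fuzzy_cmeans(table, ["f1", "f2"], k=2, m=1.05, seed=2)
        km = KMeans(2, n_init=10, random_state=0).fit_predict(
            table.data[["f1", "f2"]].to_numpy()
        )
        agree = (model.hard_labels.to_numpy() == km).mean()
        assert agree in (0.0, 1.0)  # identical up to label swap

    def test_clusters_relabelled_by_descending_size(self):
        table = make_table(
            {"x": [0.0, 0.02, 0.04, 0.06, 1.0, 1.02]}, ["case"] * 6, scale=(0, 2)
        )
        table.data["y"] = 0.5
        table.meta.append(table.meta[0].__class__("y", table.meta[0].domain, 0, 2))
        model = fuzzy_cmeans(table, ["x", "y"], k=2, seed=1)
        sizes = model.cluster_sizes
        assert sizes[0] >= sizes[1]

    def test_contract_errors(self, cases_normalised):
        cases, _ = cases_normalised
        with pytest.raises(ContractError):
            fuzzy_cmeans(cases, ["cognitive_function"], k=1)
        with pytest.raises(ContractError):
            fuzzy_cmeans(cases, ["cognitive_function"], k=2, m=1.0)


class TestValidityScan:
    def test_recovers_planted_two_feature_two_cluster_structure(self):
        hits = 0
        for seed in range(20):
            table, ranking, _ = blob_table(seed)
            rep = validity_scan(table, ranking, k_range=range(2, 7), seed=0)
            hits += rep.selected_n_features == 2 and rep.selected_k == 2
        assert hits >= 18  # >= 90% of seeds

    def test_single_blob_yields_no_confident_selection(self):
        flagged = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 30
            cols = {f"v{i}": rng.normal(0.5, 0.1, n) for i in range(4)}
            table = make_table(cols, ["case"] * n, scale=(-5, 5))
            ranking = ImportanceRanking(
                RankMethod.LAPLACIAN,
                pd.Series(np.arange(4, dtype=float), index=list(cols)),
                list(cols),
            )
            rep = validity_scan(table, ranking, k_range=range(2, 7), seed=0)
            flagged += not rep.confident
        assert flagged >= 9

    def test_selection_invariant_to_row_permutation(self):
        table, ranking, _ = blob_table(seed=3)
        rep1 = validity_scan(table, ranking, k_range=range(2, 5), seed=0)
        perm = np.random.default_rng(0).permutation(len(table.data))
        shuffled = table.subset_rows([table.participant_ids[i] for i in perm])
        rep2 = validity_scan(shuffled, ranking, k_range=range(2, 5), seed=0)
        assert rep1.selected_n_features == rep2.selected_n_features
        assert rep1.selected_k == rep2.selected_k

    def test_grid_covers_feature_and_k_ranges(self):
        table, ranking, _ = blob_table(seed=1)
        rep = validity_scan(table, ranking, k_range=range(2, 5), seed=0,
                            max_features=4)
        g = rep.grid
        assert set(g["k"]) == {2, 3, 4}
        assert g["n_features"].min() == 2
        sel = g[(g.n_features == rep.selected_n_features) & (g.k == rep.selected_k)]
        assert len(sel) == 1


class TestClusterMetrics:
    def test_tight_far_blobs_geometry(self):
        rng = np.random.default_rng(0)
        n = 20
        x = np.concatenate([rng.normal(0.1, 0.01, n), rng.normal(0.9, 0.01, n)])
        y = np.concatenate([rng.normal(0.1, 0.01, n), rng.normal(0.9, 0.01, n)])
        table = make_table({"x": x, "y": y}, ["case"] * 2 * n, scale=(0, 1))
        model = fuzzy_cmeans(table, ["x", "y"], k=2, seed=0)
        cluster_metrics(model, table)
        assert model.silhouette_index > 0.9
        assert max(model.within_cluster_distances.values()) < \
            model.between_cluster_distance / 5
        assert model.discrimination_value < -1.0  # dense, well-separated

    def test_singleton_cluster_warns_and_scores(self):
        table = make_table({"x": [0.0, 0.05, 0.1, 1.0], "y": [0.0] * 4},
                           ["case"] * 4, scale=(0, 1))
        model = fuzzy_cmeans(table, ["x", "y"], k=2, seed=0)
        with pytest.warns(UserWarning, match="singleton"):
            cluster_metrics(model, table)
        assert -1.0 <= model.silhouette_index <= 1.0
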