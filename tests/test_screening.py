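import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from painstrat.errors import DomainError
from painstrat.screening import (
    bh_fdr,
    collinearity_filter,
    force_remove,
    group_t_tests,
)
from .conftest import make_table


def brute_force_bh(p):
    """Independent step-up enumeration: q_i = min over all p_j >= p_i of
    min(1, m*p_j/rank_j), with rank_j = #{p <= p_j}."""
    p = np.asarray(p, dtype=float)
    m = p.size
    q = np.empty(m)
    for i in range(m):
        cands = []
        for j in range(m):
            if p[j] >= p[i] - 1e-15:
                rank = int(np.sum(p <= p[j] + 1e-15))
                cands.append(min(1.0, m * p[j] / rank))
        q[i] = min(cands)
    return q


class TestBHFDR:
    def test_ties_and_singleton(self):
        np.testing.assert_allclose(bh_fdr([0.01] * 10), [0.01] * 10)
        np.testing.assert_allclose(bh_fdr([0.37]), [0.37])

    def test_worked_example_against_oracle(self):
        p = [0.01, 0.04, 0.03, 0.005]
        np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    @settings(max_examples=150, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12))
    def test_matches_brute_force_and_statsmodels(self, p):
        q = bh_fdr(p)
        np.testing.assert_allclose(q, brute_force_bh(p), atol=1e-10)
        np.testing.assert_allclose(
            q, multipletests(p, method="fdr_bh")[1], atol=1e-10
        )
        assert np.all(q >= np.asarray(p) - 1e-12) and np.all(q <= 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(DomainError):
            bh_fdr([0.5, 1.2])


class TestGroupTTests:
    def test_identical_groups_select_nothing(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        table = make_table({"x": vals + vals}, ["case"] * 4 + ["control"] * 4)
        res = group_t_tests(table)
        assert res.stats.loc["x", "p"] == pytest.approx(1.0)
        assert res.n_selected_unadjusted == 0

    def test_invariant_to_row_permutation_and_affine_rescaling(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        groups = ["case"] * 6 + ["control"] * 6
        t1 = group_t_tests(make_table({"x": x}, groups)).stats.loc["x"]
        perm = rng.permutation(12)
        t2 = group_t_tests(
            make_table({"x": x[perm]}, [groups[i] for i in perm])
        ).stats.loc["x"]
        t3 = group_t_tests(make_table({"x": 3.0 * x + 7.0}, groups)).stats.loc["x"]
        assert t1["t"] == pytest.approx(t2["t"]) == pytest.approx(t3["t"])
        assert t1["p"] == pytest.approx(t2["p"]) == pytest.approx(t3["p"])

    def test_sparse_variable_marked_untestable(self):
        table = make_table(
            {"x": [1.0, np.nan, np.nan, 2.0, 3.0, 4.0]},
            ["case"] * 3 + ["control"] * 3,
        )
        res = group_t_tests(table)
        assert bool(res.stats.loc["x", "untestable"])
        assert res.n_selected_unadjusted == 0

    def test_q_never_below_p(self, cohort):
        table, _ = cohort
        res = group_t_tests(table)
        ok = ~res.stats["untestable"]
        assert (res.stats.loc[ok, "q"] >= res.stats.loc[ok, "p"] - 1e-12).all()


class TestCollinearity:
    def test_duplicated_column_drops_exactly_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        table = make_table({"a": x, "b": x.copy(), "c": rng.normal(size=20)},
                           ["case"] * 10 + ["control"] * 10)
        res = group_t_tests(table)
        collinearity_filter(table, res, candidates=["a", "b", "c"])
        assert len({"a", "b"} & set(res.removed)) == 1
        assert "c" not in res.removed

    def test_negative_duplicate_also_caught(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        table = make_table({"a": x, "b": -x}, ["case"] * 10 + ["control"] * 10)
        res = group_t_tests(table)
        collinearity_filter(table, res, candidates=["a", "b"])
        assert len(res.removed) == 1

    def test_no_false_removals_on_independent_columns(self):
        removals = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            table = make_table(
                {f"v{i}": rng.normal(size=40) for i in range(6)},
                ["case"] * 20 + ["control"] * 20,
            )
            res = group_t_tests(table)
            collinearity_filter(table, res, candidates=table.variables)
            removals += len(res.removed)
        assert removals == 0

    def test_survivors_contain_no_collinear_pair(self, cohort):
        table, _ = cohort
        res = group_t_tests(table)
        collinearity_filter(table, res, candidates=table.variables)
        keep = [v for v in table.variables if v not in res.removed]
        corr = table.data[keep].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.8 + 1e-12

    def test_zero_variance_candidate_excluded_with_reason(self):
        table = make_table({"a": [1.0] * 8, "b": np.arange(8.0)},
                           ["case"] * 4 + ["control"] * 4)
        res = group_t_tests(table)
        collinearity_filter(table, res, candidates=["a", "b"])
        assert "zero variance" in res.removed["a"]

    def test_force_remove_recorded(self):
        table = make_table({"a": np.arange(8.0), "b": np.arange(8.0) ** 2},
                           ["case"] * 4 + ["control"] * 4)
        res = group_t_tests(table)
        force_remove(res, ["a"])
        assert "force_remove" in res.removed["a"]
        assert "a" not in res.selected
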