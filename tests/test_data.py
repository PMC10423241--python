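import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from painstrat.data import (
    Domain,
    FeatureTable,
    VariableMeta,
    load_feature_table,
    normalise_01,
    save_feature_table,
    select_domain,
)
from painstrat.errors import (
    DegenerateVariableError,
    EmptySelectionError,
    SchemaError,
    TableParseError,
)
from .conftest import make_table


class TestLoadSave:
    def test_round_trip_preserves_everything(self, tmp_path):
        table = make_table(
            {"a": [1.0, 2.0, np.nan], "b": [0.1, 0.2, 0.3]},
            ["case", "case", "control"],
            domains={"a": Domain.PSYCHOSOCIAL, "b": Domain.SPINAL},
        )
        tp, mp = tmp_path / "t.csv", tmp_path / "m.csv"
        save_feature_table(table, tp, mp)
        back = load_feature_table(tp, mp)
        pd.testing.assert_frame_equal(back.data, table.data)
        pd.testing.assert_series_equal(back.group, table.group)
        assert back.meta == table.meta

    def test_missing_cells_are_nan_not_zero(self, tmp_path):
        (tmp_path / "t.csv").write_text(
            "participant_id,group,a\np1,case,\np2,control,3.5\n"
        )
        (tmp_path / "m.csv").write_text(
            "name,domain,scale_min,scale_max,higher_is_better\na,other,0,10,false\n"
        )
        ft = load_feature_table(tmp_path / "t.csv", tmp_path / "m.csv")
        assert np.isnan(ft.data.loc["p1", "a"]) and ft.data.loc["p2", "a"] == 3.5

    def test_column_without_metadata_is_schema_error(self, tmp_path):
        (tmp_path / "t.csv").write_text("participant_id,group,a,b\np1,case,1,2\n")
        (tmp_path / "m.csv").write_text(
            "name,domain,scale_min,scale_max,higher_is_better\na,other,0,10,false\n"
        )
        with pytest.raises(SchemaError, match="b"):
            load_feature_table(tmp_path / "t.csv", tmp_path / "m.csv")

    def test_duplicate_ids_and_bad_cells_rejected(self, tmp_path):
        (tmp_path / "m.csv").write_text(
            "name,domain,scale_min,scale_max,higher_is_better\na,other,0,10,false\n"
        )
        (tmp_path / "t.csv").write_text(
            "participant_id,group,a\np1,case,1\np1,control,2\n"
        )
        with pytest.raises(SchemaError, match="duplicate"):
            load_feature_table(tmp_path / "t.csv", tmp_path / "m.csv")
        (tmp_path / "t.csv").write_text("participant_id,group,a\np1,case,oops\n")
        with pytest.raises(TableParseError):
            load_feature_table(tmp_path / "t.csv", tmp_path / "m.csv")


class TestNormalise:
    def test_linear_map(self):
        table = make_table({"x": [2.0, 4.0, 6.0]}, ["case", "case", "control"])
        norm = normalise_01(table)
        assert norm.data["x"].tolist() == [0.0, 0.5, 1.0]
        assert norm.norm_params["x"] == (2.0, 6.0)

    def test_unit_range_is_fixed_point(self):
        table = make_table({"x": [0.0, 0.25, 1.0]}, ["case", "case", "control"])
        norm = normalise_01(table)
        np.testing.assert_allclose(norm.data["x"], table.data["x"], rtol=1e-12)

    def test_constant_column_raises_named_error(self):
        table = make_table({"c5": [5.0, 5.0, 5.0]}, ["case"] * 3)
        with pytest.raises(DegenerateVariableError, match="c5"):
            normalise_01(table)

    def test_rows_outside_reference_flagged_not_clipped(self):
        table = make_table({"x": [0.0, 10.0, 20.0]}, ["case", "case", "control"])
        norm = normalise_01(table, reference_rows=["P01", "P02"])
        assert norm.data.loc["P03", "x"] == 2.0
        assert bool(norm.out_of_range.loc["P03", "x"])
        assert not norm.out_of_range.loc[["P01", "P02"], "x"].any()

    @settings(max_examples=40, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=3,
            max_size=12,
            unique=True,
        )
    )
    def test_denormalise_inverts(self, values):
        table = make_table({"x": values}, ["case"] * len(values))
        norm = normalise_01(table)
        back = norm.denormalise()
        np.testing.assert_allclose(back.data["x"], table.data["x"],
                                   rtol=1e-9, atol=1e-9)


class TestSelectDomain:
    def _table(self):
        return make_table(
            {"p1": [1, 2], "p2": [3, 4], "s1": [5, 6]},
            ["case", "control"],
            domains={"p1": Domain.PSYCHOSOCIAL, "p2": Domain.PSYCHOSOCIAL,
                     "s1": Domain.SPINAL},
        )

    def test_filters_columns_keeps_rows(self):
        sub = select_domain(self._table(), Domain.PSYCHOSOCIAL)
        assert sub.variables == ["p1", "p2"]
        assert sub.participant_ids == ["P01", "P02"]

    def test_empty_selection_raises(self):
        with pytest.raises(EmptySelectionError):
            select_domain(self._table(), Domain.NERVOUS)

    def test_domains_partition_columns(self, cohort):
        table, _ = cohort
        seen = []
        for dom in Domain:
            try:
                seen += select_domain(table, dom).variables
            except EmptySelectionError:
                pass
        assert sorted(seen) == sorted(table.variables)
        assert len(seen) == len(set(seen))


def test_variable_meta_validates_scale():
    with pytest.raises(SchemaError):
        VariableMeta("x", Domain.OTHER, 5.0, 5.0)


def test_mismatched_meta_rejected():
    df = pd.DataFrame({"a": [1.0]}, index=pd.Index(["p1"], name="participant_id"))
    meta = [VariableMeta("b", Domain.OTHER, 0, 1)]
    with pytest.raises(SchemaError):
        FeatureTable(df, pd.Series(["case"], index=df.index), meta)
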