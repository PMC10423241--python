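"""Core data containers and tabular I/O.

A cohort is held as a :class:`FeatureTable`: a participants-by-variables
matrix with a case/control label per participant and a
:class:`VariableMeta` per column (biopsychosocial domain, declared scale
bounds, direction of benefit).  Unit-interval scaling produces a
:class:`NormalisedTable` that remembers its reference min/max so the
transform is invertible and reusable downstream without re-fitting.

Files are plain comma-separated text: the data table has columns
``participant_id, group, <variables...>``; the metadata sidecar has columns
``name, domain, scale_min, scale_max, higher_is_better``.  Missing values
are empty cells or the token ``NA``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateVariableError,
    EmptySelectionError,
    SchemaError,
    TableParseError,
)

CASE = "case"
CONTROL = "control"
_MISSING_TOKENS = {"", "NA", "na", "NaN", "nan"}


class Domain(str, Enum):
    """The biopsychosocial variable families plus a catch-all."""

    NERVOUS = "nervous"
    SPINAL = "spinal"
    PSYCHOSOCIAL = "psychosocial"
    OTHER = "other"


@dataclass(frozen=True)
class VariableMeta:
    """Per-variable metadata: domain, declared scale, direction of benefit."""

    name: str
    domain: Domain
    scale_min: float
    scale_max: float
    higher_is_better: bool = False

    def __post_init__(self):
        object.__setattr__(self, "domain", Domain(self.domain))
        if not self.scale_min < self.scale_max:
            raise SchemaError(
                f"variable {self.name!r}: scale_min ({self.scale_min}) must be "
                f"< scale_max ({self.scale_max})"
            )


@dataclass
class FeatureTable:
    """Participants x variables matrix with group labels and metadata.

    ``data`` is indexed by participant id; ``group`` is aligned to it and
    takes values ``"case"``/``"control"``; ``meta`` is aligned to the
    columns of ``data`` in order.
    """

    data: pd.DataFrame
    group: pd.Series
    meta: list[VariableMeta]

    def __post_init__(self):
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise SchemaError(f"duplicate participant ids: {dupes}")
        if len(self.group) != len(self.data):
            raise SchemaError("group labels and rows are misaligned")
        bad = set(self.group.unique()) - {CASE, CONTROL}
        if bad:
            raise SchemaError(f"group labels must be case/control, got {sorted(bad)}")
        names = [m.name for m in self.meta]
        if names != list(self.data.columns):
            raise SchemaError(
                "metadata does not match data columns: "
                f"meta={names}, columns={list(self.data.columns)}"
            )
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names in metadata")
        self.group = self.group.reindex(self.data.index)

    # -- convenience accessors -------------------------------------------------
    @property
    def participant_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_cases(self) -> int:
        return int((self.group == CASE).sum())

    @property
    def n_controls(self) -> int:
        return int((self.group == CONTROL).sum())

    def meta_for(self, name: str) -> VariableMeta:
        for m in self.meta:
            if m.name == name:
                return m
        raise KeyError(name)

    def cases(self) -> "FeatureTable":
        return self.subset_rows(self.group[self.group == CASE].index)

    def controls(self) -> "FeatureTable":
        return self.subset_rows(self.group[self.group == CONTROL].index)

    def subset_rows(self, ids: Iterable[str]) -> "FeatureTable":
        ids = list(ids)
        return replace(
            self, data=self.data.loc[ids], group=self.group.loc[ids], meta=list(self.meta)
        )

    def subset_columns(self, names: Sequence[str]) -> "FeatureTable":
        names = list(names)
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise SchemaError(f"unknown variables: {missing}")
        meta = [self.meta_for(n) for n in names]
        return replace(self, data=self.data[names], group=self.group, meta=meta)


@dataclass
class NormalisedTable(FeatureTable):
    """A FeatureTable mapped to the unit interval per variable.

    ``norm_params`` maps variable name -> (reference min, reference max).
    Rows outside the reference set may fall outside [0, 1]; those cells are
    flagged in ``out_of_range``.
    """

    norm_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    reference_ids: list[str] = field(default_factory=list)
    out_of_range: pd.DataFrame | None = None

    def denormalise(self) -> FeatureTable:
        """Invert the unit scaling using the stored reference min/max."""
        raw = self.data.copy()
        for name in raw.columns:
            lo, hi = self.norm_params[name]
            raw[name] = raw[name] * (hi - lo) + lo
        return FeatureTable(data=raw, group=self.group.copy(), meta=list(self.meta))


# -- I/O -----------------------------------------------------------------------


def read_metadata(meta_path: str | Path) -> list[VariableMeta]:
    df = pd.read_csv(meta_path, dtype=str)
    required = {"name", "domain", "scale_min", "scale_max", "higher_is_better"}
    if not required.issubset(df.columns):
        raise SchemaError(
            f"metadata must have columns {sorted(required)}, got {list(df.columns)}"
        )
    metas = []
    for _, row in df.iterrows():
        try:
            metas.append(
                VariableMeta(
                    name=row["name"],
                    domain=Domain(row["domain"]),
                    scale_min=float(row["scale_min"]),
                    scale_max=float(row["scale_max"]),
                    higher_is_better=str(row["higher_is_better"]).strip().lower()
                    in {"1", "true", "yes"},
                )
            )
        except ValueError as exc:
            raise SchemaError(f"bad metadata row for {row['name']!r}: {exc}") from exc
    return metas


def load_feature_table(table_path: str | Path, meta_path: str | Path) -> FeatureTable:
    """Read a cohort table plus its metadata sidecar and validate the pair.

    Missing cells (empty or ``NA``) become NaN, never zero.  Every data
    column must be covered by the sidecar; ids must be unique.
    """
    raw = pd.read_csv(table_path, dtype=str, keep_default_na=False)
    for col in ("participant_id", "group"):
        if col not in raw.columns:
            raise SchemaError(f"table must have a {col!r} column")
    metas = read_metadata(meta_path)
    by_name = {m.name: m for m in metas}
    var_cols = [c for c in raw.columns if c not in ("participant_id", "group")]
    uncovered = [c for c in var_cols if c not in by_name]
    if uncovered:
        raise SchemaError(f"columns without metadata: {uncovered}")

    def parse_cell(col: str, cell: str) -> float:
        if cell.strip() in _MISSING_TOKENS:
            return np.nan
        try:
            return float(cell)
        except ValueError:
            raise TableParseError(f"non-numeric cell in {col!r}: {cell!r}") from None

    data = pd.DataFrame(
        {c: [parse_cell(c, v) for v in raw[c]] for c in var_cols},
        index=pd.Index(raw["participant_id"], name="participant_id"),
    )
    group = pd.Series(raw["group"].values, index=data.index, name="group")
    return FeatureTable(data=data, group=group, meta=[by_name[c] for c in var_cols])


def save_feature_table(
    table: FeatureTable, table_path: str | Path, meta_path: str | Path | None = None
) -> None:
    out = table.data.copy()
    out.insert(0, "group", table.group)
    out.to_csv(table_path, index=True, na_rep="NA")
    if meta_path is not None:
        pd.DataFrame(
            {
                "name": [m.name for m in table.meta],
                "domain": [m.domain.value for m in table.meta],
                "scale_min": [m.scale_min for m in table.meta],
                "scale_max": [m.scale_max for m in table.meta],
                "higher_is_better": [m.higher_is_better for m in table.meta],
            }
        ).to_csv(meta_path, index=False)


# -- transforms ----------------------------------------------------------------


def normalise_01(
    table: FeatureTable, reference_rows: Sequence[str] | None = None
) -> NormalisedTable:
    """Min-max scale every variable to [0, 1] over a reference row set.

    value' = (value - min_ref) / (max_ref - min_ref).  Rows outside the
    reference set are transformed with the same parameters and may leave
    the unit interval; such cells are flagged, not clipped.
    """
    ref_ids = list(reference_rows) if reference_rows is not None else table.participant_ids
    if not ref_ids:
        raise EmptySelectionError("reference_rows must be non-empty")
    ref = table.data.loc[ref_ids]
    params: dict[str, tuple[float, float]] = {}
    scaled = table.data.copy().astype(float)
    for name in table.variables:
        lo, hi = float(np.nanmin(ref[name])), float(np.nanmax(ref[name]))
        if not hi > lo:
            raise DegenerateVariableError(name)
        params[name] = (lo, hi)
        scaled[name] = (table.data[name] - lo) / (hi - lo)
    oor = (scaled < 0) | (scaled > 1)
    return NormalisedTable(
        data=scaled,
        group=table.group.copy(),
        meta=list(table.meta),
        norm_params=params,
        reference_ids=ref_ids,
        out_of_range=oor,
    )


def apply_norm_params(
    table: FeatureTable, params: dict[str, tuple[float, float]]
) -> NormalisedTable:
    """Re-apply previously fitted unit-scaling parameters to another table."""
    missing = [v for v in table.variables if v not in params]
    if missing:
        raise SchemaError(f"no normalisation parameters for: {missing}")
    scaled = table.data.copy().astype(float)
    for name in table.variables:
        lo, hi = params[name]
        scaled[name] = (table.data[name] - lo) / (hi - lo)
    oor = (scaled < 0) | (scaled > 1)
    return NormalisedTable(
        data=scaled,
        group=table.group.copy(),
        meta=list(table.meta),
        norm_params={v: params[v] for v in table.variables},
        reference_ids=[],
        out_of_range=oor,
    )


def select_domain(table: FeatureTable, domain: Domain | str) -> FeatureTable:
    """Restrict columns to one biopsychosocial domain; rows unchanged."""
    domain = Domain(domain)
    names = [m.name for m in table.meta if m.domain == domain]
    if not names:
        raise EmptySelectionError(f"no variables in domain {domain.value!r}")
    return table.subset_columns(names)
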