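import numpy as np
import pandas as pd
import pytest

from painstrat.data import CASE, CONTROL, Domain, FeatureTable, VariableMeta
from painstrat.synthetic import default_config, generate_cohort


def make_table(values, groups, domains=None, ids=None, scale=(-1000.0, 1000.0)):
    """Small FeatureTable from a dict of columns for unit tests."""
    df = pd.DataFrame(values)
    n = len(df)
    ids = ids or [f"P{i + 1:02d}" for i in range(n)]
    df.index = pd.Index(ids, name="participant_id")
    domains = domains or {c: Domain.OTHER for c in df.columns}
    meta = [
        VariableMeta(c, domains.get(c, Domain.OTHER), scale[0], scale[1])
        for c in df.columns
    ]
    return FeatureTable(
        df.astype(float),
        pd.Series(list(groups), index=df.index, name="group"),
        meta,
    )


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort (21 controls, 16+5 cases) plus latent labels."""
    table, latent = generate_cohort(default_config(seed=11))
    return table, latent


@pytest.fixture(scope="session")
def cases_normalised(cohort):
    from painstrat.data import normalise_01

    table, latent = cohort
    return normalise_01(table).cases(), latent[latent != "control"]
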