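import numpy as np
import pandas as pd
import pytest

from stabmi.cohort import CohortTable, VariableSpec


def make_table(columns: dict, specs=None, mask: dict | None = None) -> CohortTable:
    """Build a CohortTable from plain arrays; default specs are a binary
    outcome named 'y' plus continuous candidates."""
    df = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in columns.items()})
    if specs is None:
        specs = []
        for name in df.columns:
            if name == "y":
                specs.append(VariableSpec("y", "outcome_raw", "binary"))
            else:
                specs.append(VariableSpec(name, "candidate", "continuous"))
    m = pd.DataFrame({k: np.asarray(v, dtype=bool) for k, v in mask.items()}) \
        if mask is not None else None
    if m is not None:
        for c in df.columns:
            if c not in m.columns:
                m[c] = False
        df = df.where(~m[df.columns], np.nan)
    return CohortTable(df, specs, m)


def logistic_cohort(rng, n, betas: dict, intercept=0.0):
    """Draw independent standard-normal predictors and a logistic outcome."""
    cols = {name: rng.standard_normal(n) for name in betas}
    lp = intercept + sum(b * cols[name] for name, b in betas.items())
    cols["y"] = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
    return make_table(cols)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
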