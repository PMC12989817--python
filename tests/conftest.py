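import numpy as np
import pandas as pd
import pytest

from turbomap import SimParams, generate_catalog
from turbomap.ingest import LogMatrix, SampleDesign


def make_logmatrix(values, columns, index=None, symbols=None) -> LogMatrix:
    """Build a LogMatrix from a plain array for unit tests."""
    values = np.asarray(values, dtype=float)
    index = index or [f"P{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=pd.Index(index, name="protein_id"),
                      columns=columns)
    syms = pd.Series(symbols or [f"G{i}" for i in range(values.shape[0])],
                     index=df.index)
    return LogMatrix(df, syms, ["log2"])


def make_design(rows) -> SampleDesign:
    return SampleDesign(pd.DataFrame(
        rows, columns=["sample_id", "group", "assay", "replicate"]))


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    return SimParams(n_proteins=300, seed=11)


@pytest.fixture(scope="session")
def small_catalog(small_params):
    return generate_catalog(small_params)


@pytest.fixture()
def two_cohort_design():
    """3 control + 3 treated AP samples."""
    rows = [(f"AP_control_{r}", "control", "AP", r) for r in (1, 2, 3)]
    rows += [(f"AP_N_term_{r}", "N_term", "AP", r) for r in (1, 2, 3)]
    return make_design(rows)
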