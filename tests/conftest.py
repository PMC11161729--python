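import numpy as np
import pandas as pd
import pytest

from ptxrank import default_config, generate_cohorts, normalize_counts
from ptxrank.containers import CountMatrix, NORMALIZED_SC


@pytest.fixture(scope="session")
def cohorts():
    """One default synthetic cohort pair shared across tests."""
    return generate_cohorts(default_config(seed=42))


@pytest.fixture(scope="session")
def norm_discovery(cohorts):
    return normalize_counts(cohorts.discovery)


def make_matrix(values, proteins=None, samples=None, layer=NORMALIZED_SC):
    arr = np.asarray(values, dtype=float)
    proteins = proteins or [f"P{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return CountMatrix(pd.DataFrame(arr, index=proteins, columns=samples), layer=layer)
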