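import numpy as np
import pandas as pd
import pytest

from tmepipe.io_core import ExpressionMatrix
from tmepipe.synthetic import SimConfig, default_reference, simulate_cohort


@pytest.fixture(scope="session")
def reference():
    return default_reference()


@pytest.fixture(scope="session")
def small_cohort():
    """One 80-sample default-condition cohort shared across tests."""
    cfg = SimConfig(seed=11, n_samples=80)
    expr, clin, truth = simulate_cohort(cfg)
    return cfg, expr, clin, truth


@pytest.fixture()
def toy_expression():
    df = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
        index=["GA", "GB", "GC"], columns=["S1", "S2"],
    )
    return ExpressionMatrix(df, unit="counts")


def make_expr(arr, genes=None, samples=None, unit="logcpm"):
    arr = np.asarray(arr, float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), unit=unit)
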