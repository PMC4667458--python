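import numpy as np
import pandas as pd
import pytest

from lipidtrn.expression import ExpressionMatrix
from lipidtrn.filtering import compute_log_ratios
from lipidtrn.synthetic import DEFAULT_TIME_GRID, simulate_toy_metabolic_model


@pytest.fixture(scope="session")
def default_times():
    return np.asarray(DEFAULT_TIME_GRID)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_expression(values, times, ids=None) -> ExpressionMatrix:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    ids = ids or [f"t{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(pd.DataFrame(values, index=ids, columns=list(times)))


def ratios_from_planted(rows: dict[str, np.ndarray], times) -> "LogRatioMatrix":
    """Build a log-ratio matrix whose profiles are exactly the planted rows."""
    x0 = 100.0
    fpkm = {tid: (x0 + 1.0) * np.exp2(np.asarray(r, dtype=float)) - 1.0 for tid, r in rows.items()}
    expr = ExpressionMatrix(pd.DataFrame(fpkm, index=list(times)).T)
    return compute_log_ratios(expr)


@pytest.fixture(scope="session")
def chain_model():
    return simulate_toy_metabolic_model("chain")


@pytest.fixture(scope="session")
def branch_model():
    return simulate_toy_metabolic_model("branch")


@pytest.fixture(scope="session")
def isozyme_model():
    return simulate_toy_metabolic_model("isozyme")
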