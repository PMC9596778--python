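import numpy as np
import pandas as pd
import pytest

from irscore import CohortDataset, ExpressionMatrix, SignatureCollection, SurvivalTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_expr(rng):
    """20 genes x 5 samples, log-scale-looking values."""
    genes = [f"G{i:02d}" for i in range(20)]
    samples = [f"S{j}" for j in range(5)]
    data = pd.DataFrame(rng.normal(6, 1, size=(20, 5)), index=genes, columns=samples)
    return ExpressionMatrix(data)


@pytest.fixture
def small_sigs(rng):
    genes = [f"G{i:02d}" for i in range(20)]
    sets = {}
    for k in range(3):
        sets[f"SET{k}"] = list(rng.choice(genes, size=5, replace=False))
    return SignatureCollection(sets)


@pytest.fixture
def toy_cohort(rng):
    """Small cohort with survival, no planted structure."""
    n = 40
    genes = [f"G{i:02d}" for i in range(30)]
    samples = [f"P{j:02d}" for j in range(n)]
    expr = ExpressionMatrix(
        pd.DataFrame(rng.normal(6, 1, size=(30, n)), index=genes, columns=samples)
    )
    time = rng.exponential(10, size=n).round(3)
    event = rng.integers(0, 2, size=n)
    event[0] = 1  # guarantee at least one event
    surv = SurvivalTable(pd.DataFrame({"time": time, "event": event}, index=samples))
    return CohortDataset("toy", expr, surv)


def make_survival(times, events, ids=None) -> SurvivalTable:
    ids = ids or [f"s{i}" for i in range(len(times))]
    return SurvivalTable(pd.DataFrame({"time": times, "event": events}, index=ids))
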