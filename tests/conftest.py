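import numpy as np
import pandas as pd
import pytest

from deqms.datamodel import DesignSpec, ProteinMatrix


@pytest.fixture
def two_group_design():
    return DesignSpec(
        sample_to_group={
            "s1": "A",
            "s2": "A",
            "s3": "A",
            "s4": "B",
            "s5": "B",
            "s6": "B",
        }
    )


@pytest.fixture
def small_matrix(two_group_design):
    """10 proteins x 6 samples with varied counts; seeded Gaussian."""
    rng = np.random.default_rng(7)
    ids = [f"P{i}" for i in range(10)]
    values = pd.DataFrame(
        rng.normal(0, 0.3, size=(10, 6)),
        index=ids,
        columns=list(two_group_design.sample_to_group),
    )
    count = pd.Series(rng.integers(1, 15, size=10), index=ids)
    return ProteinMatrix(values=values, count=count)


def make_matrix(values, counts=None, samples=None):
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    ids = [f"P{i}" for i in range(p)]
    samples = samples or [f"s{j + 1}" for j in range(n)]
    counts = counts if counts is not None else np.ones(p, dtype=int)
    return ProteinMatrix(
        values=pd.DataFrame(values, index=ids, columns=samples),
        count=pd.Series(counts, index=ids),
    )
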