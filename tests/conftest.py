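import warnings

import numpy as np
import pandas as pd
import pytest

from pkdnet import simulate as sim
from pkdnet.datatypes import ExpressionMatrix, SampleMetadata


@pytest.fixture(autouse=True)
def _quiet():
    # generators and degenerate-case paths emit warnings by design;
    # individual tests assert them explicitly where they matter
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture
def small_matrix():
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [1.0, 1.5, 2.5, 3.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(values)


@pytest.fixture
def study():
    """One seeded two-module study: (matrix, metadata, true labels)."""
    plans = [
        sim.ModulePlan(1, 50, genotype_effect=1.5),
        sim.ModulePlan(2, 40, age_effect=1.0),
    ]
    return sim.gen_expression(plans, 300, seed=7)


@pytest.fixture
def two_group_meta():
    def make(n_ctrl, n_mut, prefix="s"):
        ids = [f"{prefix}{i}" for i in range(n_ctrl + n_mut)]
        return SampleMetadata(
            pd.DataFrame(
                {
                    "genotype": ["control"] * n_ctrl + ["mutant"] * n_mut,
                    "age": "P14",
                    "batch": "B0",
                    "split": "test",
                },
                index=pd.Index(ids, name="sample_id"),
            )
        )

    return make


def make_expression(values: np.ndarray, prefix="G", sample_prefix="S") -> ExpressionMatrix:
    values = np.asarray(values, float)
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"{prefix}{i}" for i in range(values.shape[0])],
            columns=[f"{sample_prefix}{j}" for j in range(values.shape[1])],
        )
    )
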