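import numpy as np
import pandas as pd
import pytest

import refstab as rs


@pytest.fixture
def micro_rq() -> pd.DataFrame:
    """Hand-checkable 3-gene x 2-sample RQ matrix.

    A and B share a constant ratio; C diverges by two doublings in sample 2.
    """
    return pd.DataFrame(
        [[1.0, 2.0], [1.0, 2.0], [1.0, 8.0]],
        index=["A", "B", "C"],
        columns=["s1", "s2"],
    )


@pytest.fixture
def study_dataset():
    """A seeded study-shaped dataset: all genes truly stable."""
    return rs.simulate(rs.default_study_config(seed=42))


@pytest.fixture
def study_rq(study_dataset) -> rs.RQMatrix:
    table, eff, _ = study_dataset
    filtered, _ = rs.qc_filter(table)
    return rs.to_relative_quantities(filtered, eff)


def random_rq(rng: np.random.Generator, n_genes: int, n_samples: int) -> pd.DataFrame:
    """Random positive RQ matrix on a realistic log2 scale."""
    values = np.exp2(rng.normal(0.0, 1.0, size=(n_genes, n_samples)))
    return pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
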