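import numpy as np
import pandas as pd
import pytest

import covdeg as cd


@pytest.fixture(scope="session")
def default_fixture():
    """The desk-scale study: 5 unbalanced classes, 2 series, 50 planted genes."""
    design = cd.default_design(seed=11)
    m, truth = cd.simulate_dataset(design)
    return m, truth


@pytest.fixture(scope="session")
def discovery(default_fixture):
    """Full qc -> merge -> normalize -> degs chain on the default fixture."""
    m, truth = default_fixture
    return cd.run_discovery(m), truth


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples, two classes, hand-enterable values."""
    values = pd.DataFrame(
        [[0.0, 2.0, 4.0, 6.0], [1.0, 1.0, 1.0, 1.0], [5.0, 4.0, 3.0, 2.0]],
        index=["G1", "G2", "G3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return cd.ExpressionMatrix(
        values=values,
        class_labels=pd.Series(["A", "A", "B", "B"]),
        series_ids=pd.Series(["x", "x", "x", "x"]),
    )


def make_labeled_matrix(x, classes, gene_prefix="G"):
    """ExpressionMatrix from an array and per-sample class labels."""
    x = np.asarray(x, dtype=float)
    values = pd.DataFrame(
        x,
        index=[f"{gene_prefix}{i}" for i in range(x.shape[0])],
        columns=[f"s{j}" for j in range(x.shape[1])],
    )
    return cd.ExpressionMatrix(values=values, class_labels=pd.Series(list(classes)))
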