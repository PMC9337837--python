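import pytest

from cinorigin.io_formats import LabelVector
from cinorigin.mrmr import mrmr_rank
from cinorigin.preprocessing import discretize_three_state
from cinorigin.synthetic_data import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Generator defaults: 3x100 cells, 2000 genes, 20 markers/class, seed 7."""
    return generate_dataset(GeneratorConfig())


@pytest.fixture(scope="session")
def default_ranked(default_dataset):
    """mRMR top-100 ranking of the default dataset (alpha=1 discretization)."""
    matrix, labels, _ = default_dataset
    disc = discretize_three_state(matrix)
    return mrmr_rank(disc, labels, k=100)


@pytest.fixture
def tiny_matrix():
    """4 cells x 3 genes with one all-zero gene and one constant gene."""
    from cinorigin.io_formats import ExpressionMatrix

    return ExpressionMatrix(
        ["c1", "c2", "c3", "c4"],
        ["gA", "gZERO", "gCONST"],
        [[1.0, 0.0, 5.0], [2.0, 0.0, 5.0], [0.0, 0.0, 5.0], [4.0, 0.0, 5.0]],
    )


@pytest.fixture
def two_class_labels():
    return LabelVector(["c1", "c2", "c3", "c4"], ["A", "A", "B", "B"])
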