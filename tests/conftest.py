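import numpy as np
import pytest

from scmarker_ifs import ExpressionDataset, desk_spec, generate


@pytest.fixture(scope="session")
def desk_data():
    """The small six-class benchmark dataset with its planted-marker truth."""
    return generate(desk_spec(seed=1))


@pytest.fixture(scope="session")
def separator_dataset():
    """60 cells, 20 genes; gene 'g_sep' separates the two classes perfectly
    with a wide margin, all other genes are i.i.d. noise."""
    rng = np.random.default_rng(42)
    n_per = 30
    noise = rng.uniform(0, 5, size=(2 * n_per, 19))
    sep = np.concatenate([rng.uniform(0, 1, n_per), rng.uniform(9, 10, n_per)])
    matrix = np.column_stack([noise[:, :10], sep, noise[:, 10:]])
    gene_ids = [f"g{j:02d}" for j in range(10)] + ["g_sep"] + [
        f"g{j:02d}" for j in range(10, 19)
    ]
    return ExpressionDataset(
        cell_ids=[f"c{i:03d}" for i in range(2 * n_per)],
        gene_ids=gene_ids,
        matrix=matrix,
        labels=["A"] * n_per + ["B"] * n_per,
    )


def make_labeled(matrix, labels, prefix="cell"):
    matrix = np.asarray(matrix, dtype=float)
    return ExpressionDataset(
        cell_ids=[f"{prefix}{i}" for i in range(matrix.shape[0])],
        gene_ids=[f"g{j}" for j in range(matrix.shape[1])],
        matrix=matrix,
        labels=list(labels),
    )
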