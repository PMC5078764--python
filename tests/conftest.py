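import numpy as np
import pytest

from ncproj.data import (
    AssociationMatrix,
    Dataset,
    EntityIndex,
    FamilyMatrix,
    SimilarityMatrix,
)


def random_similarity(rng, n, labels=None, role="MM"):
    """Random symmetric similarity matrix in [0, 1] with unit diagonal."""
    raw = rng.random((n, n))
    values = (raw + raw.T) / 2.0
    np.fill_diagonal(values, 1.0)
    index = EntityIndex.from_iterable(
        labels if labels is not None else (f"e{i}" for i in range(n))
    )
    return SimilarityMatrix(index, values, role)


def random_dataset(seed, n_mirna=8, n_disease=6, density=0.3, with_family=True):
    """Small random dataset where every entity has at least one association."""
    rng = np.random.default_rng(seed)
    mlabels = [f"m{i}" for i in range(n_mirna)]
    dlabels = [f"d{j}" for j in range(n_disease)]
    mm = random_similarity(rng, n_mirna, mlabels, "MM")
    dd = random_similarity(rng, n_disease, dlabels, "DD")
    values = (rng.random((n_mirna, n_disease)) < density).astype(np.int8)
    # guarantee a non-degenerate association matrix
    for i in range(n_mirna):
        if values[i].sum() == 0:
            values[i, rng.integers(n_disease)] = 1
    for j in range(n_disease):
        if values[:, j].sum() == 0:
            values[rng.integers(n_mirna), j] = 1
    as_matrix = AssociationMatrix(
        EntityIndex.from_iterable(mlabels),
        EntityIndex.from_iterable(dlabels),
        values,
    )
    fam = None
    if with_family:
        fam_values = np.eye(n_mirna, dtype=np.int8)
        half = n_mirna // 2
        fam_values[:half, :half] = 1
        fam = FamilyMatrix(as_matrix.mirna_index, fam_values)
    return Dataset(mm=mm, dd=dd, as_matrix=as_matrix, fam=fam)


@pytest.fixture
def small_dataset():
    return random_dataset(seed=7)
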