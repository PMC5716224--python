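import numpy as np
import pytest

from cellpipe import Dataset, ExpressionMatrix, SampleMetadata


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_matrix(values, value_space="raw", prefix_g="g", prefix_s="s"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        [f"{prefix_g}{i + 1}" for i in range(values.shape[0])],
        [f"{prefix_s}{j + 1}" for j in range(values.shape[1])],
        values,
        value_space,
    )


def make_dataset(values, value_space="raw", **meta_cols):
    m = make_matrix(values, value_space)
    cols = {k: [str(x) for x in v] for k, v in meta_cols.items()}
    return Dataset(m, SampleMetadata(list(m.sample_ids), cols))


@pytest.fixture
def matrix_factory():
    return make_matrix


@pytest.fixture
def dataset_factory():
    return make_dataset
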