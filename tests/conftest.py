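import numpy as np
import pandas as pd
import pytest

from layerstrata import ExpressionMatrix, LayerSpec, generate_dataset


@pytest.fixture(scope="session")
def two_layer_dataset():
    """Small planted two-layer cohort shared across tests.

    Layer A: 60 genes, two balanced groups; layer B: 80 genes, three
    groups; 360 noise genes; 150 samples.
    """
    specs = [
        LayerSpec("A", 60, 2, (0.5, 0.5), 2.0, 1.0),
        LayerSpec("B", 80, 3, (1 / 3, 1 / 3, 1 / 3), 2.0, 1.0),
    ]
    return generate_dataset(specs, 150, 360, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_matrix(array, gene_prefix="g", sample_prefix="s"):
    """Wrap a genes x samples ndarray in an ExpressionMatrix."""
    array = np.asarray(array, dtype=float)
    return ExpressionMatrix(pd.DataFrame(
        array,
        index=[f"{gene_prefix}{i:03d}" for i in range(array.shape[0])],
        columns=[f"{sample_prefix}{j:03d}" for j in range(array.shape[1])],
    ))
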