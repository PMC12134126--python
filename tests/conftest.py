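import numpy as np
import pandas as pd
import pytest

from delatlas.expression import ExpressionMatrix


def make_matrix(values, scale_tag="log2", gene_prefix="g", sample_prefix="s", meta=None):
    """ExpressionMatrix from a 2-D array with generated ids."""
    values = np.asarray(values, dtype=float)
    genes = [f"{gene_prefix}{i:03d}" for i in range(values.shape[0])]
    samples = [f"{sample_prefix}{j:03d}" for j in range(values.shape[1])]
    frame = pd.DataFrame(values, index=genes, columns=samples)
    sm = pd.DataFrame(meta, index=samples) if meta is not None else pd.DataFrame()
    return ExpressionMatrix(frame, scale_tag=scale_tag, sample_meta=sm)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_block_matrix():
    """10 samples in two blocks with identical within-block profiles."""
    profile_a = np.array([3.0, 1.0, 2.0, 5.0, 0.5])
    profile_b = np.array([0.5, 4.0, 1.0, 0.0, 3.0])
    cols = np.column_stack([profile_a] * 5 + [profile_b] * 5)
    return make_matrix(cols, scale_tag="log2"), [f"s{j:03d}" for j in range(5)]
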