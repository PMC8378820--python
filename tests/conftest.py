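import numpy as np
import pandas as pd
import pytest

from rescue_seq import ExpressionMatrix


def make_matrix(values, classes, space="linear", genes=None):
    """Build an ExpressionMatrix from a 2-D array and a class-per-sample list."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    counts = {}
    samples = []
    for cls in classes:
        counts[cls] = counts.get(cls, 0) + 1
        samples.append(f"{cls}_{counts[cls]}")
    frame = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionMatrix(frame, pd.Series(classes, index=samples), space)


@pytest.fixture
def three_group_matrix():
    """9 samples in 3 classes, 4 genes with distinct group structure."""
    rng = np.random.default_rng(7)
    base = rng.normal(6.0, 0.3, size=(4, 9))
    base[0, 3:6] += 2.0          # disease-shifted gene
    base[1, 3:] += 1.5           # disease+treated-shifted gene
    return make_matrix(base, ["control"] * 3 + ["disease"] * 3 + ["treated"] * 3,
                       space="log2")
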