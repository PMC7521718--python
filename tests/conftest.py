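import numpy as np
import pytest

import zonerecon as zr


@pytest.fixture(scope="session")
def shipped_truth():
    """The default 1000-gene truth used by the recovery-style tests."""
    return zr.generate_truth(n_genes=1000, n_cells=66, seed=1)


@pytest.fixture(scope="session")
def deep_matrix(shipped_truth):
    return zr.simulate_counts(shipped_truth, zr.DEFAULT_REGIMES["deep"])


@pytest.fixture(scope="session")
def deep_order(shipped_truth, deep_matrix):
    return zr.wavecrest_order(deep_matrix, shipped_truth.markers(), seed=0)


@pytest.fixture()
def tiny_matrix():
    """3 genes x 4 cells with one spike-in row."""
    values = np.array(
        [
            [1.0, 0.0, 2.0, 3.0],
            [4.0, 5.0, 0.0, 1.0],
            [0.0, 2.0, 1.0, 0.0],
        ]
    )
    return zr.ExpressionMatrix(
        values=values,
        gene_ids=["Glul", "Cyp2e1", "ERCC-0001"],
        cell_ids=["c1", "c2", "c3", "c4"],
        layer=zr.RAW_COUNTS,
        spike_flags=[False, False, True],
    )
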