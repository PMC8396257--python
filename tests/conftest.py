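import numpy as np
import pandas as pd
import pytest

import revertome as rv


@pytest.fixture(scope="session")
def small_sim():
    """A modest four-condition experiment with all planted classes."""
    cfg = rv.SimConfig(n_genes=2000, seed=7)
    cm, truth = rv.generate(cfg)
    return cfg, cm, truth


@pytest.fixture()
def toy_counts():
    """Tiny hand-checkable count matrix (4 genes x 4 samples, 2 conditions)."""
    counts = pd.DataFrame(
        {
            "control_1": [10, 100, 30, 0],
            "control_2": [12, 90, 28, 1],
            "A_1": [50, 95, 31, 0],
            "A_2": [48, 110, 29, 2],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
    )
    design = pd.DataFrame(
        {"condition": ["control", "control", "A", "A"], "replicate": [1, 2, 1, 2]},
        index=pd.Index(counts.columns, name="sample_id"),
    )
    lengths = pd.Series([1000, 2000, 1500, 800], index=counts.index, name="length")
    return rv.CountMatrix(counts, lengths, design)


def bh_oracle(p):
    """Independent brute-force BH step-up: q_i = min_{j>=i}(p_(j) m / j)."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q
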