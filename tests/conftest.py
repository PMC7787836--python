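import numpy as np
import pandas as pd
import pytest

from pairdx import GenePairClassifier, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """Small multi-platform dataset with 8 planted pairs (fast, reused read-only)."""
    cfg = SimConfig(n_samples=160, n_genes=40, n_informative_pairs=8, seed=5)
    expr, truth = simulate_dataset(cfg)
    return cfg, expr, truth


@pytest.fixture(scope="session")
def tiny_expr():
    """4 genes x 3 samples with known orderings."""
    return pd.DataFrame(
        {
            "s1": [2.0, 1.0, 3.0, 0.5],
            "s2": [1.0, 2.0, 2.0, 2.0],
            "s3": [1.5, 1.5, 0.1, 4.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )


@pytest.fixture(scope="session")
def trained_small(small_sim):
    """SDSAE fitted on the first 120 samples of the small dataset (short schedule)."""
    _, expr, truth = small_sim
    train_cols = expr.columns[:120]
    model = GenePairClassifier.from_expression(expr[train_cols], truth.labels[:120])
    results = model.fit(epochs_pretrain=20, epochs_finetune=60, seed=3)
    return model, results


def numeric_gradient(f, arr, eps=1e-6):
    """Central finite differences of scalar f with respect to array arr (in place)."""
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = arr[i]
        arr[i] = orig + eps
        fp = f()
        arr[i] = orig - eps
        fm = f()
        arr[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


def max_rel_err(a, b):
    return float(np.max(np.abs(a - b) / (np.abs(a) + np.abs(b) + 1e-10)))
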