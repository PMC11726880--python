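import numpy as np
import pandas as pd
import pytest

from cashde.datasets import CASE, CONTROL, ExpressionDataset


def make_dataset(case: np.ndarray, ctrl: np.ndarray, genes=None) -> ExpressionDataset:
    """Build a labeled dataset from per-group matrices (genes x samples)."""
    case = np.atleast_2d(np.asarray(case, dtype=float))
    ctrl = np.atleast_2d(np.asarray(ctrl, dtype=float))
    n_g = case.shape[0]
    genes = genes or [f"g{i}" for i in range(n_g)]
    samples = [f"c{i}" for i in range(case.shape[1])] + [
        f"k{i}" for i in range(ctrl.shape[1])
    ]
    values = pd.DataFrame(np.hstack([case, ctrl]), index=genes, columns=samples)
    groups = pd.Series([CASE] * case.shape[1] + [CONTROL] * ctrl.shape[1], index=samples)
    return ExpressionDataset(values, groups)


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    rng = np.random.default_rng(42)
    return make_dataset(rng.normal(7, 1, (10, 4)), rng.normal(7, 1, (10, 5)))


def random_boolean_matrix(rng, n_genes, n_samples) -> np.ndarray:
    return (rng.random((n_genes, n_samples)) < rng.uniform(0.1, 0.9)).astype(np.uint8)
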