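import numpy as np
import pandas as pd
import pytest

from cellrecap.datatypes import ExpressionMatrix
from cellrecap.preprocess import CellGroupSignal


def make_signal(y_ref, y_con, x_ref=None, x_con=None, name="group"):
    """Build a pair of (signal, covariate) CellGroupSignals from raw arrays."""
    y = np.concatenate([np.asarray(y_ref, float), np.asarray(y_con, float)])
    cells = [f"r{i}" for i in range(len(y_ref))] + \
            [f"c{i}" for i in range(len(y_con))]
    labels = pd.Series(["reference"] * len(y_ref) + ["contrast"] * len(y_con),
                       index=cells)
    sig = CellGroupSignal(values=pd.Series(y, index=cells), labels=labels,
                          group_name=name, n_genes_used=1)
    if x_ref is None:
        return sig
    x = np.concatenate([np.asarray(x_ref, float), np.asarray(x_con, float)])
    cov = CellGroupSignal(values=pd.Series(x, index=cells), labels=labels,
                          group_name="cc", n_genes_used=1)
    return sig, cov


def ancova_oracle(y_ref, y_con, x_ref, x_con):
    """Brute-force normal-equations solve of the 3-parameter common-slope
    design; independent of the package's fitting path."""
    y = np.concatenate([y_ref, y_con])
    x = np.concatenate([x_ref, x_con])
    g = np.concatenate([np.zeros(len(y_ref)), np.ones(len(y_con))])
    X = np.column_stack([np.ones_like(x), g, x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta  # (intercept, delta_intercept, slope)


@pytest.fixture
def tiny_matrix():
    values = pd.DataFrame(
        [[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]],
        index=["g1", "g2", "g3"], columns=["cellA", "cellB"])
    labels = pd.Series(["reference", "contrast"], index=["cellA", "cellB"])
    return ExpressionMatrix(values=values, cell_labels=labels)


@pytest.fixture
def small_config():
    from cellrecap.simulate import SimulationConfig
    return SimulationConfig(n_genes_per_stratum=8, n_cells_per_population=40,
                            n_cc_genes=10, n_background_genes=60, seed=3)
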