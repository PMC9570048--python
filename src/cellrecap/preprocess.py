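"""Quantile normalization and per-cell gene-group signals.

The analysis contrasts the mean expression of a gene group (e.g. the genes
of one phylostratum) against the mean expression of the mitotic cell-cycle
signature (GO:0000278), cell by cell. Before averaging, the matrix is
quantile-normalized across cells so that all cells share one value
distribution; group means are taken on the log2 scale and back-transformed
(geometric-mean semantics), and the signature genes can be removed from the
tested group to avoid the circularity of regressing a group on itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix


@dataclass
class CellGroupSignal:
    """Per-cell back-transformed mean expression of one gene group."""

    values: pd.Series          # cell_id -> signal (linear scale)
    labels: pd.Series          # cell_id -> population label
    group_name: str
    n_genes_used: int

    def in_population(self, population: str) -> np.ndarray:
        mask = (self.labels == population).to_numpy()
        if not mask.any():
            raise KeyError(f"no cells labeled {population!r}")
        return self.values.to_numpy()[mask]


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every cell onto the across-cell mean value distribution.

    Each cell's sorted value vector is replaced by the mean of all cells'
    sorted vectors; within-cell rank order is preserved. Genes tied within a
    cell receive the mean of the reference quantile values their rank range
    spans, which makes the result deterministic and permutation-invariant.
    """
    vals = matrix.values.to_numpy(dtype=float)
    n_genes, n_cells = vals.shape
    if n_cells < 2:
        raise ValueError("quantile normalization needs at least 2 cells")
    order = np.argsort(vals, axis=0, kind="stable")
    ranked = np.take_along_axis(vals, order, axis=0)
    reference = ranked.mean(axis=1)
    out = np.empty_like(vals)
    for j in range(n_cells):
        col_sorted = ranked[:, j]
        assigned = reference.copy()
        # average reference values over runs of tied observations
        start = 0
        for end in range(1, n_genes + 1):
            if end == n_genes or col_sorted[end] != col_sorted[start]:
                if end - start > 1:
                    assigned[start:end] = reference[start:end].mean()
                start = end
        out[order[:, j], j] = assigned
    df = pd.DataFrame(out, index=matrix.gene_ids, columns=matrix.cell_ids)
    return ExpressionMatrix(values=df, cell_labels=matrix.cell_labels)


def group_mean_per_cell(matrix: ExpressionMatrix, group: Iterable[str],
                        log_offset: float = 1.0,
                        group_name: str = "group") -> CellGroupSignal:
    """Back-transformed per-cell mean of ``log2(value + log_offset)``.

    The back-transform ``2**mean - log_offset`` (floored at 0) inverts the
    transform for a single gene and yields a shifted geometric mean in
    general.
    """
    group = set(group)
    present = [g for g in matrix.gene_ids if g in group]
    if not present:
        raise ValueError(f"gene group {group_name!r} has no genes in the matrix")
    sub = matrix.values.loc[present].to_numpy(dtype=float)
    if log_offset == 0 and (sub <= 0).any():
        raise ValueError(
            f"group {group_name!r} has non-positive values; use log_offset > 0")
    logmean = np.log2(sub + log_offset).mean(axis=0)
    back = np.maximum(np.exp2(logmean) - log_offset, 0.0)
    return CellGroupSignal(
        values=pd.Series(back, index=matrix.cell_ids),
        labels=matrix.cell_labels,
        group_name=group_name,
        n_genes_used=len(present),
    )


def cell_cycle_signal(matrix: ExpressionMatrix, cc_genes: Iterable[str],
                      tested_group: Iterable[str],
                      remove_overlap: bool = True,
                      log_offset: float = 1.0
                      ) -> tuple[CellGroupSignal, frozenset[str]]:
    """Cell-cycle signature signal plus the (optionally purged) tested group.

    When ``remove_overlap`` is set, signature genes are removed from the
    tested group so that the regression covariate and the response share no
    genes.
    """
    cc_genes = set(cc_genes)
    tested = frozenset(tested_group)
    signal = group_mean_per_cell(matrix, cc_genes, log_offset=log_offset,
                                 group_name="cell_cycle_signature")
    if remove_overlap:
        purged = tested - cc_genes
        if tested and not purged:
            raise ValueError(
                "removing cell-cycle signature genes empties the tested group")
        tested = purged
    return signal, tested
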