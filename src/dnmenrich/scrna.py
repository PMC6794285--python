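"""Per-cell-type enrichment of a single gene in labeled single-cell expression.

Given a normalized cells × genes expression matrix with a cell-type label per
cell, each type is compared one-vs-rest for the gene of interest:

* an odds ratio of *detection* (expression above a threshold, default > 0)
  in-type vs all other cells, with a 0.5 correction on zero cells;
* a two-sided Wilcoxon rank-sum test on the expression values in-type vs the
  rest (exact enumeration for small untied groups, normal approximation with
  tie correction otherwise);
* Bonferroni adjustment of the rank-sum p over the number of types tested.

Output rows are ordered by mean in-type expression, descending.  The module
consumes pre-processed values; it performs no normalization or clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse
from scipy import stats

from .genesets import odds_ratio_2x2

logger = logging.getLogger(__name__)

__all__ = ["CellExpressionInput", "celltype_enrichment", "CellTypeEnrichmentModel"]

#: Below this per-group cell count the rank-sum test is evaluated exactly.
_EXACT_MAX_N = 50


@dataclass
class CellExpressionInput:
    """Labeled single-cell expression focused on one gene of interest.

    ``expr`` is cells × genes (dense or scipy sparse), ``genes`` names the
    columns, ``cell_types`` labels every row.
    """

    expr: np.ndarray | sparse.spmatrix
    genes: Sequence[str]
    cell_types: Sequence[str]
    gene_of_interest: str

    def __post_init__(self) -> None:
        n_cells, n_genes = self.expr.shape
        if len(self.cell_types) != n_cells:
            raise ValueError("every cell must have a type label")
        if len(self.genes) != n_genes:
            raise ValueError("gene name list does not match matrix columns")
        if self.gene_of_interest not in set(self.genes):
            raise ValueError(f"gene {self.gene_of_interest!r} not present in the matrix")

    @property
    def gene_values(self) -> np.ndarray:
        """Expression vector of the gene of interest across cells."""
        j = list(self.genes).index(self.gene_of_interest)
        col = self.expr[:, j]
        if sparse.issparse(col):
            return np.asarray(col.todense()).ravel()
        return np.asarray(col, dtype=float).ravel()

    @classmethod
    def from_mtx(
        cls,
        mtx_path: str | Path,
        genes_path: str | Path,
        cells_path: str | Path,
        gene_of_interest: str,
        cell_type_column: str = "cell_type",
        cells_are_rows: bool = True,
    ) -> "CellExpressionInput":
        """Load MatrixMarket triplets + genes TSV + cell-metadata TSV."""
        m = spio.mmread(str(mtx_path)).tocsr()
        if not cells_are_rows:
            m = m.T.tocsr()
        genes = pd.read_csv(genes_path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
        meta = pd.read_csv(cells_path, sep="\t")
        if cell_type_column not in meta.columns:
            raise ValueError(f"cell metadata lacks column {cell_type_column!r}")
        return cls(m, genes, meta[cell_type_column].astype(str).tolist(), gene_of_interest)

    @classmethod
    def from_anndata(cls, adata, gene_of_interest: str, cell_type_key: str = "cell_type"):
        """Build from an AnnData object (obs key names the cell types)."""
        return cls(
            adata.X,
            [str(g) for g in adata.var_names],
            adata.obs[cell_type_key].astype(str).tolist(),
            gene_of_interest,
        )

    def collapse_types(self, mapping: Mapping[str, str]) -> "CellExpressionInput":
        """Collapse fine cluster labels to broad types via a user-supplied map."""
        return CellExpressionInput(
            self.expr,
            self.genes,
            [mapping.get(t, t) for t in self.cell_types],
            self.gene_of_interest,
        )


def _ranksum_p(in_vals: np.ndarray, rest_vals: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum probability.

    Exact when both groups have <= 50 cells and the pooled values are
    untied; normal approximation with tie correction (and continuity
    correction) otherwise.
    """
    pooled = np.concatenate([in_vals, rest_vals])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = max(len(in_vals), len(rest_vals)) <= _EXACT_MAX_N
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(in_vals, rest_vals, alternative="two-sided", method=method)
    return float(res.pvalue)


def celltype_enrichment(
    inp: CellExpressionInput,
    detection_threshold: float = 0.0,
    min_cells: int = 2,
) -> pd.DataFrame:
    """One-vs-rest enrichment/depletion of the gene of interest per cell type.

    Returns a DataFrame with columns ``cell_type, n_cells, mean_expr,
    detection_rate, odds_ratio, p_raw, p_adj`` sorted by ``mean_expr``
    descending.  Types with fewer than ``min_cells`` cells are excluded with
    a warning.  Requires at least two usable types.
    """
    values = inp.gene_values
    labels = np.asarray(inp.cell_types)
    types = [t for t in pd.unique(labels)]
    usable = []
    for t in types:
        n = int((labels == t).sum())
        if n < min_cells:
            logger.warning("cell type %r has only %d cell(s); excluded", t, n)
        else:
            usable.append(t)
    if len(usable) < 2:
        raise ValueError("at least 2 cell types with >= min_cells cells are required")

    detected = values > detection_threshold
    rows = []
    n_tests = len(usable)
    for t in usable:
        mask = labels == t
        in_vals, rest_vals = values[mask], values[~mask]
        a = int(detected[mask].sum())
        b = int(mask.sum()) - a
        c = int(detected[~mask].sum())
        d = int((~mask).sum()) - c
        if (b == 0 and d == 0) or (a == 0 and c == 0):
            odds = 1.0  # detection is degenerate (all or none detected everywhere)
        else:
            odds = odds_ratio_2x2(a, b, c, d)
        if np.ptp(np.concatenate([in_vals, rest_vals])) == 0:
            p = 1.0  # constant expression: exchangeable null, no test to run
        else:
            p = _ranksum_p(in_vals, rest_vals)
        rows.append(
            {
                "cell_type": t,
                "n_cells": int(mask.sum()),
                "mean_expr": float(in_vals.mean()),
                "detection_rate": a / int(mask.sum()),
                "odds_ratio": odds,
                "p_raw": p,
                "p_adj": min(1.0, p * n_tests),
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values("mean_expr", ascending=False).reset_index(drop=True)


class CellTypeEnrichmentModel:
    """Model-object wrapper around :func:`celltype_enrichment`."""

    def __init__(self, inp: CellExpressionInput, detection_threshold: float = 0.0, min_cells: int = 2):
        self.input = inp
        self.detection_threshold = detection_threshold
        self.min_cells = min_cells

    def fit(self) -> pd.DataFrame:
        return celltype_enrichment(self.input, self.detection_threshold, self.min_cells)
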