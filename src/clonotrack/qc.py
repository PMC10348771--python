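"""Per-cell QC, log-normalization and grouped panel averaging.

QC follows the strict-inequality reading of the stated criteria: a cell is
excluded iff its mitochondrial fraction exceeds 0.25 or it expresses fewer
than 200 genes.  Boundary cells (exactly 25% mitochondrial, exactly 200
genes) pass.  Normalization is the standard per-cell library-size scaling:
``value = ln(1 + count · scale_factor / total)`` with scale factor 10,000.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .tenx import CountMatrix

__all__ = ["compute_qc", "filter_cells", "lognormalize", "panel_average",
           "MAX_MITO_FRACTION", "MIN_GENES"]

logger = logging.getLogger(__name__)

MAX_MITO_FRACTION = 0.25
MIN_GENES = 200


def compute_qc(
    matrix: CountMatrix,
    mito_genes: set[str] | None = None,
    max_mito: float = MAX_MITO_FRACTION,
    min_genes: int = MIN_GENES,
    blacklist: set[str] | None = None,
) -> pd.DataFrame:
    """Per-cell QC table: total counts, expressed genes, mito fraction, verdict.

    ``mito_genes`` defaults to all features prefixed ``MT-``.  ``blacklist``
    is an optional explicit set of barcodes to fail regardless of metrics
    (hook for externally flagged low-quality cells; empty by default).
    Fails a cell iff mito_fraction > max_mito (strict) or n_genes <
    min_genes (strict), or it is blacklisted.
    """
    if mito_genes is None:
        mito_genes = {g for g in matrix.genes if g.startswith("MT-")}
    unknown = set(mito_genes) - set(matrix.genes)
    if unknown:
        raise ValueError(f"mito genes not in features: {sorted(unknown)[:5]}")
    X = sp.csc_matrix(matrix.counts)
    totals = np.asarray(X.sum(axis=0)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=0)).ravel()
    mito_idx = [i for i, g in enumerate(matrix.genes) if g in mito_genes]
    mito_totals = (
        np.asarray(X[mito_idx, :].sum(axis=0)).ravel() if mito_idx else np.zeros_like(totals)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(totals > 0, mito_totals / np.maximum(totals, 1), 0.0)
    pass_qc = (mito_fraction <= max_mito) & (n_genes >= min_genes)
    df = pd.DataFrame(
        {
            "barcode": matrix.barcodes,
            "total_counts": totals.astype(int),
            "n_genes": n_genes.astype(int),
            "mito_fraction": mito_fraction,
            "pass_qc": pass_qc,
        }
    )
    if blacklist:
        df.loc[df["barcode"].isin(blacklist), "pass_qc"] = False
    return df


def filter_cells(matrix: CountMatrix, qc: pd.DataFrame) -> CountMatrix:
    """Restrict the matrix to QC-passing barcodes, preserving order."""
    covered = set(qc["barcode"])
    missing = [bc for bc in matrix.barcodes if bc not in covered]
    if missing:
        raise ValueError(f"QC table does not cover {len(missing)} barcodes")
    keep = set(qc.loc[qc["pass_qc"], "barcode"])
    if not keep:
        logger.warning("filter_cells: no cells pass QC")
    return matrix.subset_cells([bc for bc in matrix.barcodes if bc in keep])


def lognormalize(matrix: CountMatrix, scale_factor: float = 10_000.0) -> CountMatrix:
    """Library-size log-normalization: ln(1 + count · scale_factor / total).

    Zeros map to zeros, so the sparsity pattern is preserved.  A zero-total
    cell raises (such a cell cannot pass QC and signals a pipeline bug).
    """
    X = sp.csc_matrix(matrix.counts, copy=True).astype(float)
    totals = np.asarray(X.sum(axis=0)).ravel()
    if np.any(totals == 0):
        raise ValueError("lognormalize: zero-total cell encountered (filter cells first)")
    X = X.multiply(scale_factor / totals)  # broadcasts over columns
    X = sp.csc_matrix(X)
    np.log1p(X.data, out=X.data)
    return CountMatrix(genes=list(matrix.genes), barcodes=list(matrix.barcodes), counts=X)


def panel_average(
    normalized: CountMatrix,
    groups: dict[str, str],
    panel: list[str],
    zscore: bool = False,
) -> pd.DataFrame:
    """Mean normalized expression per (group label, gene) for a gene panel.

    ``groups`` maps barcode → label and must cover every barcode.  With
    ``zscore=True`` each gene column is z-scaled across labels (heatmap
    export convention).  Labels with no cells yield NaN rows with a warning.
    """
    missing_genes = [g for g in panel if g not in normalized.genes]
    if missing_genes:
        raise ValueError(f"panel genes not in features: {missing_genes}")
    unlabeled = [bc for bc in normalized.barcodes if bc not in groups]
    if unlabeled:
        raise ValueError(f"{len(unlabeled)} barcodes have no group label")
    labels = sorted(set(groups.values()))
    gene_idx = [normalized.gene_index(g) for g in panel]
    sub = sp.csr_matrix(normalized.counts)[gene_idx, :]
    col_labels = np.array([groups[bc] for bc in normalized.barcodes])
    rows = {}
    for label in labels:
        cols = np.flatnonzero(col_labels == label)
        if cols.size == 0:
            logger.warning("panel_average: group %r is empty", label)
            rows[label] = np.full(len(panel), np.nan)
        else:
            rows[label] = np.asarray(sub[:, cols].mean(axis=1)).ravel()
    df = pd.DataFrame.from_dict(rows, orient="index", columns=panel)
    df.index.name = "group"
    if zscore:
        mu = df.mean(axis=0)
        sd = df.std(axis=0, ddof=0).replace(0, np.nan)
        df = (df - mu) / sd
    return df
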