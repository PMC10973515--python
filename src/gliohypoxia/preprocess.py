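"""Cell quality-control filtering and log-normalisation.

QC removes cells with fewer than 1000 UMIs, fewer than 400 detected genes,
or more than 25% mitochondrial counts — strict inequalities, so a cell
sitting exactly on a boundary (1000 UMIs, 400 genes, 25% mito) is kept.
Normalisation is the standard library-size log transform:
``ln(1 + scale * count / total)`` with scale 10^4.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import _compute_cell_totals, logger


@dataclass(frozen=True)
class QcThresholds:
    """Removal thresholds: a cell is dropped iff total_umi < min_umi, or
    n_genes_detected < min_genes, or mito_fraction > max_mito."""

    min_umi: int = 1000
    min_genes: int = 400
    max_mito: float = 0.25

    def __post_init__(self) -> None:
        if self.min_umi < 0 or self.min_genes < 0:
            raise ValueError("count thresholds must be non-negative")
        if not 0.0 <= self.max_mito <= 1.0:
            raise ValueError("max_mito must lie in [0, 1]")


def filter_cells(cells: ad.AnnData, thr: QcThresholds = QcThresholds()) -> ad.AnnData:
    """Apply QC, returning the retained cells in their original order.

    Retains exactly the cells with ``total_umi >= min_umi`` and
    ``n_genes_detected >= min_genes`` and ``mito_fraction <= max_mito``.
    Per-criterion removal counts are logged; an all-removed result is an
    explicit warning, not an error.
    """
    if "total_umi" not in cells.obs.columns:
        _compute_cell_totals(cells)
    obs = cells.obs
    low_umi = obs["total_umi"] < thr.min_umi
    low_genes = obs["n_genes_detected"] < thr.min_genes
    high_mito = obs["mito_fraction"] > thr.max_mito
    keep = ~(low_umi | low_genes | high_mito)
    logger.info(
        "filter_cells: %d/%d retained (removed: %d low-UMI, %d low-gene, %d high-mito)",
        int(keep.sum()), cells.n_obs,
        int(low_umi.sum()), int(low_genes.sum()), int(high_mito.sum()),
    )
    if cells.n_obs and not keep.any():
        logger.warning("filter_cells: all %d cells removed by QC", cells.n_obs)
    return cells[np.asarray(keep)].copy()


def qc_report(cells: ad.AnnData, thr: QcThresholds = QcThresholds()) -> pd.DataFrame:
    """Per-criterion QC summary (cells failing each criterion, and overall)."""
    if "total_umi" not in cells.obs.columns:
        _compute_cell_totals(cells)
    obs = cells.obs
    low_umi = obs["total_umi"] < thr.min_umi
    low_genes = obs["n_genes_detected"] < thr.min_genes
    high_mito = obs["mito_fraction"] > thr.max_mito
    keep = ~(low_umi | low_genes | high_mito)
    return pd.DataFrame({
        "criterion": ["low_umi", "low_genes", "high_mito", "retained", "total"],
        "threshold": [thr.min_umi, thr.min_genes, thr.max_mito, np.nan, np.nan],
        "n_cells": [int(low_umi.sum()), int(low_genes.sum()),
                    int(high_mito.sum()), int(keep.sum()), cells.n_obs],
    })


def log_normalize(cells: ad.AnnData, scale: float = 10_000.0,
                  layer: str = "lognorm") -> ad.AnnData:
    """Add a log-normalised layer: ``ln(1 + scale * count / total_umi)``.

    Cells with zero total UMIs get an all-zero row with a warning.  Sparsity
    is preserved (zero counts map to zero).  Returns the same AnnData for
    chaining.
    """
    if "total_umi" not in cells.obs.columns:
        _compute_cell_totals(cells)
    totals = cells.obs["total_umi"].to_numpy().astype(float)
    n_zero = int((totals == 0).sum())
    if n_zero:
        logger.warning("log_normalize: %d cells with zero total UMI left all-zero",
                       n_zero)
    safe = np.where(totals > 0, totals, 1.0)
    X = cells.X
    if sp.issparse(X):
        norm = X.tocsr().astype(np.float64)
        row_scale = scale / safe
        norm = sp.diags(row_scale) @ norm
        norm.data = np.log1p(norm.data)
        cells.layers[layer] = norm.tocsr()
    else:
        cells.layers[layer] = np.log1p(scale * np.asarray(X, float) / safe[:, None])
    return cells
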