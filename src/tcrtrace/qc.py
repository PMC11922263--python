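"""Cell and gene quality filters, library-size normalization, gene scaling.

Filters reproduce a standard droplet scRNA-seq T-cell workflow: cells must
express CD3 (>0 counts), carry 200-5,000 detected features, stay under a
mitochondrial-fraction ceiling and express at least one housekeeping gene;
genes must be detected in >=3 cells. Expression is then log-normalized per
10,000 counts (ln(1 + 1e4 * c / total)) and z-scaled per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
from scipy import sparse

log = logging.getLogger(__name__)

#: order in which cell filters are applied; attrition is attributed to the
#: first failing filter
CELL_FILTERS = ("cd3", "features", "mito", "housekeeping")


@dataclass
class QCParams:
    min_cells_per_gene: int = 3
    min_features: int = 200
    max_features: int = 5000
    cd3_gene: str = "Cd3e"
    require_cd3_positive: bool = True
    housekeeping_genes: tuple = ("Actb", "B2m", "Gapdh")
    max_mito_fraction: float = 0.10
    mito_prefix: str = "mt-"

    def __post_init__(self):
        if self.min_features >= self.max_features:
            raise ValueError("min_features must be < max_features")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in [0, 1]")


@dataclass
class QCReport:
    """Per-filter attrition; input cells = retained + sum of removals."""

    n_input_cells: int
    n_retained_cells: int
    removed: dict = field(default_factory=dict)  # filter name -> cells removed
    n_input_genes: int = 0
    n_retained_genes: int = 0

    def as_dict(self) -> dict:
        return {
            "n_input_cells": self.n_input_cells,
            "n_retained_cells": self.n_retained_cells,
            "removed": dict(self.removed),
            "n_input_genes": self.n_input_genes,
            "n_retained_genes": self.n_retained_genes,
        }


def _column(X, j: int) -> np.ndarray:
    col = X[:, j]
    return np.asarray(col.todense()).ravel() if sparse.issparse(col) else np.asarray(col).ravel()


def filter_cells(adata: ad.AnnData, params: QCParams | None = None) -> tuple[ad.AnnData, QCReport]:
    """Apply the cell filters in :data:`CELL_FILTERS` order, then drop genes
    detected in fewer than ``min_cells_per_gene`` of the retained cells.

    Each removed cell is attributed to the first filter it fails. Raises
    ``KeyError`` if the CD3 or housekeeping genes are absent from the matrix.
    """
    params = params or QCParams()
    X = adata.X
    var_names = list(adata.var_names)
    if params.require_cd3_positive and params.cd3_gene not in adata.var_names:
        raise KeyError(f"CD3 gene {params.cd3_gene!r} not in the gene list")
    hk = [g for g in params.housekeeping_genes if g in adata.var_names]
    if params.housekeeping_genes and not hk:
        raise KeyError(f"none of the housekeeping genes {params.housekeeping_genes} are in the gene list")

    Xc = sparse.csr_matrix(X) if not sparse.issparse(X) else X.tocsr()
    # nnz would count explicit zeros, so count strictly positive entries
    detected = np.asarray((Xc > 0).sum(axis=1)).ravel()
    totals = np.asarray(Xc.sum(axis=1)).ravel()
    mito_idx = [j for j, g in enumerate(var_names) if g.startswith(params.mito_prefix)]
    mito = (
        np.asarray(Xc[:, mito_idx].sum(axis=1)).ravel() if mito_idx else np.zeros(Xc.shape[0])
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)

    passes = {
        "cd3": (
            _column(Xc, var_names.index(params.cd3_gene)) > 0
            if params.require_cd3_positive
            else np.ones(Xc.shape[0], bool)
        ),
        "features": (detected >= params.min_features) & (detected <= params.max_features),
        "mito": mito_frac <= params.max_mito_fraction,
        "housekeeping": (
            np.asarray((Xc[:, [var_names.index(g) for g in hk]] > 0).sum(axis=1)).ravel() > 0
            if hk
            else np.ones(Xc.shape[0], bool)
        ),
    }

    removed: dict[str, int] = {}
    alive = np.ones(Xc.shape[0], bool)
    for name in CELL_FILTERS:
        fail = alive & ~passes[name]
        removed[name] = int(fail.sum())
        alive &= passes[name]

    kept = adata[alive].copy()
    genes_detected_in = np.asarray((sparse.csr_matrix(kept.X) > 0).sum(axis=0)).ravel()
    gene_keep = genes_detected_in >= params.min_cells_per_gene
    report = QCReport(
        n_input_cells=adata.n_obs,
        n_retained_cells=int(alive.sum()),
        removed=removed,
        n_input_genes=adata.n_vars,
        n_retained_genes=int(gene_keep.sum()),
    )
    kept = kept[:, gene_keep].copy()
    log.info(
        "QC: %d -> %d cells (removed %s), %d -> %d genes",
        report.n_input_cells, report.n_retained_cells, removed,
        report.n_input_genes, report.n_retained_genes,
    )
    return kept, report


def normalize_cp10k_log(X) -> sparse.csr_matrix:
    """ln(1 + 10,000 * count / cell_total) per entry; sparsity preserved.

    Raises ``ValueError`` on a zero-total cell (impossible after QC).
    """
    Xc = sparse.csr_matrix(X, dtype=np.float64)
    totals = np.asarray(Xc.sum(axis=1)).ravel()
    if (totals <= 0).any():
        raise ValueError(f"{int((totals <= 0).sum())} cells have zero total counts")
    out = Xc.copy()
    scale = 1e4 / totals
    out.data = out.data * np.repeat(scale, np.diff(out.indptr))
    out.data = np.log1p(out.data)
    return out


def scale_genes(X, max_value: float = 10.0) -> np.ndarray:
    """Center each gene to mean 0 and unit variance (ddof=1), clip to
    ``+-max_value``; constant genes become all-zero. Returns dense."""
    A = np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X, dtype=np.float64)
    A = A.astype(np.float64, copy=True)
    mu = A.mean(axis=0)
    sd = A.std(axis=0, ddof=1) if A.shape[0] > 1 else np.zeros(A.shape[1])
    out = A - mu
    nz = sd > 0
    out[:, nz] /= sd[nz]
    out[:, ~nz] = 0.0
    np.clip(out, -max_value, max_value, out=out)
    return out


def normalize_adata(adata: ad.AnnData) -> ad.AnnData:
    """Attach the log-normalized layer to a filtered AnnData."""
    adata = adata.copy()
    adata.layers["lognorm"] = normalize_cp10k_log(adata.X)
    return adata
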