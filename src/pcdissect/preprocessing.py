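"""Cell quality control, log-normalization, gene selection, and pseudobulking.

All operations accept an AnnData with raw UMI counts in ``.X`` (cells x
genes, sparse).  Log-normalized expression is stored in
``.layers["lognorm"]`` using the natural logarithm:

    e_{g,c} = ln(1e4 * n_{g,c} / N_c + 1)

where the per-cell total N_c excludes genes that account for more than 20%
of the UMIs of *any* cell (immunoglobulin genes dominate plasma-cell
libraries and would otherwise compress everything else).  Excluded genes
are still normalized and reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "QCThresholds",
    "qc_filter_cells",
    "log_normalize",
    "select_analysis_genes",
    "pseudobulk",
    "cpm_filter_genes",
]

SEX_GENES = ("XIST", "RPS4Y1")
IG_PREFIXES = ("IGH", "IGK", "IGL")


@dataclass(frozen=True)
class QCThresholds:
    """Cell-level QC cut-offs; all inequalities are strict."""

    max_mito_fraction: float = 0.15
    min_genes: int = 200
    max_umis: int = 50_000
    max_genes: int = 4_000

    def __post_init__(self):
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be below max_genes")
        if min(self.max_mito_fraction, self.min_genes, self.max_umis) <= 0:
            raise ValueError("thresholds must be positive")


def _mito_mask(adata: ad.AnnData, mito_gene_flags=None) -> np.ndarray:
    if mito_gene_flags is not None:
        flags = np.asarray(mito_gene_flags, dtype=bool)
        if flags.shape[0] != adata.n_vars:
            raise ValueError("mito flags must align with genes")
        return flags
    if "is_mito" in adata.var:
        return adata.var["is_mito"].to_numpy(dtype=bool)
    return np.array([s.startswith("MT-") for s in adata.var_names])


def qc_filter_cells(
    adata: ad.AnnData,
    thresholds: QCThresholds = QCThresholds(),
    mito_gene_flags=None,
) -> ad.AnnData:
    """Retain cells with mito fraction < max, genes detected in (min, max), UMIs < max.

    Returns a filtered copy; cell order is preserved.  If no cell survives,
    an empty AnnData is returned with a warning (not an exception).
    """
    X = sp.csr_matrix(adata.X)
    totals = np.asarray(X.sum(axis=1)).ravel()
    n_genes = X.getnnz(axis=1)
    mito = _mito_mask(adata, mito_gene_flags)
    mito_counts = np.asarray(X[:, mito].sum(axis=1)).ravel() if mito.any() else np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 1.0)
    keep = (
        (mito_frac < thresholds.max_mito_fraction)
        & (n_genes > thresholds.min_genes)
        & (totals < thresholds.max_umis)
        & (n_genes < thresholds.max_genes)
    )
    if not keep.any():
        warnings.warn("no cells passed QC filtering; returning empty result")
    return adata[keep].copy()


def log_normalize(
    adata: ad.AnnData,
    target_sum: float = 1e4,
    max_gene_share: float = 0.2,
    inplace: bool = True,
) -> ad.AnnData:
    """Natural-log normalization with dominant-gene exclusion from N_c.

    Genes whose share of any single cell's UMIs exceeds ``max_gene_share``
    are excluded from every cell's total N_c but are themselves still
    normalized.  Cells whose N_c is zero after exclusion are dropped with a
    warning.  Results in ``.layers["lognorm"]``; the excluded-gene mask in
    ``.var["excluded_from_total"]``.
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("cannot normalize an empty matrix")
    X = sp.csr_matrix(adata.X).astype(np.float64)
    raw_totals = np.asarray(X.sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        inv = np.where(raw_totals > 0, 1.0 / np.maximum(raw_totals, 1e-300), 0.0)
    frac = X.multiply(inv[:, None]).tocsc()
    max_share = np.zeros(adata.n_vars)
    if frac.nnz:
        max_share = frac.max(axis=0).toarray().ravel()
    excluded = max_share > max_gene_share

    n_c = np.asarray(X[:, ~excluded].sum(axis=1)).ravel()
    dead = n_c <= 0
    out = adata if inplace else adata.copy()
    if dead.any():
        warnings.warn(f"dropping {int(dead.sum())} cells with zero denominator after exclusion")
        out = out[~dead].copy()
        X = X[~dead]
        n_c = n_c[~dead]
    scaled = X.multiply((target_sum / n_c)[:, None]).tocsr()
    scaled.data = np.log1p(scaled.data)
    out.layers["lognorm"] = scaled
    out.var["excluded_from_total"] = excluded
    out.obs["n_c"] = n_c
    return out


def _ig_mask(gene_meta: pd.DataFrame) -> np.ndarray:
    if "is_ig" in gene_meta:
        return gene_meta["is_ig"].to_numpy(dtype=bool)
    return np.array([s.startswith(IG_PREFIXES) for s in gene_meta.index])


def select_analysis_genes(gene_meta: pd.DataFrame, mode: str = "nmf") -> np.ndarray:
    """Boolean mask of genes kept for an analysis mode.

    Immunoglobulin-locus genes are always excluded (clonally expressed,
    dominate disease signatures).  The sex genes XIST and RPS4Y1 are
    additionally excluded for dimensionality-reduction-type analyses
    (``mode`` in {"nmf", "pca", "umap", "clustering"}) but kept for
    differential expression (``mode="de"``).
    """
    mode = mode.lower()
    if mode not in ("nmf", "pca", "umap", "clustering", "de"):
        raise ValueError(f"unknown mode {mode!r}")
    mask = ~_ig_mask(gene_meta)
    if mode != "de":
        mask &= ~gene_meta.index.isin(SEX_GENES)
    return mask


def pseudobulk(adata: ad.AnnData, cell_subset=None, max_share: float = 0.05) -> pd.Series:
    """CPM-like pseudobulk of a cell subset.

    Gene counts are summed across cells; the denominator is the total count
    ignoring genes that account for more than ``max_share`` of the summed
    counts (those genes are still reported, only excluded from the
    denominator); the ratio is scaled by 1e6.
    """
    X = sp.csr_matrix(adata.X)
    if cell_subset is not None:
        X = X[np.asarray(cell_subset)]
    if X.shape[0] == 0:
        raise ValueError("pseudobulk of an empty cell subset")
    sums = np.asarray(X.sum(axis=0)).ravel().astype(float)
    total = sums.sum()
    if total <= 0:
        raise ValueError("pseudobulk of an all-zero subset")
    dominant = sums / total > max_share
    denom = sums[~dominant].sum()
    if denom <= 0:
        warnings.warn("all genes dominant; falling back to the full total")
        denom = total
    return pd.Series(sums / denom * 1e6, index=adata.var_names, name="pseudobulk_cpm")


def cpm_filter_genes(
    pseudosample_counts: pd.DataFrame,
    frac_abnormal: np.ndarray,
    frac_normal: np.ndarray,
    ig_mask=None,
    min_cpm: float = 5.0,
    min_cell_fraction: float = 0.05,
) -> np.ndarray:
    """Gene mask for the cross-patient pseudosample comparison.

    Keeps genes with plain CPM >= ``min_cpm`` in at least one pseudosample,
    expressed in at least ``min_cell_fraction`` of abnormal *or* normal
    cells, and not immunoglobulin genes.

    Parameters
    ----------
    pseudosample_counts : genes x pseudosamples summed counts.
    frac_abnormal, frac_normal : per-gene fraction of abnormal / normal
        cells with nonzero counts.
    """
    counts = pseudosample_counts.to_numpy(dtype=float)
    if counts.shape[1] < 1:
        raise ValueError("need at least one pseudosample")
    cpm = counts / counts.sum(axis=0, keepdims=True) * 1e6
    pass_cpm = (cpm >= min_cpm).any(axis=1)
    fa = np.asarray(frac_abnormal, dtype=float)
    fn = np.asarray(frac_normal, dtype=float)
    pass_cells = (fa >= min_cell_fraction) | (fn >= min_cell_fraction)
    if ig_mask is None:
        ig = np.array([s.startswith(IG_PREFIXES) for s in pseudosample_counts.index])
    else:
        ig = np.asarray(ig_mask, dtype=bool)
    return pass_cpm & pass_cells & ~ig
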