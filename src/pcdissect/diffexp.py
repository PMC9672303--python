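"""Within-patient differential expression and pseudosample preparation.

Each mixed sample's abnormal cells are compared against the *same patient's*
normal cells with a two-sided Wilcoxon rank-sum test (normal approximation
with tie and continuity correction), Benjamini-Hochberg correction across
the genes tested in that patient, and a fold-change statistic computed on
log-normalized expression:

    FC = (exp(mean_A) - 1 + offset) / (exp(mean_B) - 1 + offset)

where the offset defaults to half the smallest nonzero log-normalized value
in the dataset (it replaces the conventional 1e-9 pseudo-offset to avoid
inflated fold changes of lowly expressed genes).  A gene is flagged as
differentially expressed when q < 0.1 and |ln FC| > ln 1.5.

The cross-patient pseudosample preparation (summed counts + design
covariates) feeds an external model-fitting step; only its inputs are
produced here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .preprocessing import cpm_filter_genes, select_analysis_genes

__all__ = [
    "FoldChangeSpec",
    "compute_default_offset",
    "group_fold_change",
    "wilcoxon_rank_sum",
    "within_patient_de",
    "prepare_pseudosample_tables",
    "cross_patient_max_q",
    "DEG_Q_THRESHOLD",
    "DEG_LFC_THRESHOLD",
]

DEG_Q_THRESHOLD = 0.1
DEG_LFC_THRESHOLD = float(np.log(1.5))


@dataclass(frozen=True)
class FoldChangeSpec:
    """Offset of the fold-change statistic.

    The default 0.126 is the half-minimum nonzero log-normalized value of a
    reference CD138+ cohort; recompute it for the dataset at hand with
    :func:`compute_default_offset`.
    """

    offset: float = 0.126

    def __post_init__(self):
        if self.offset <= 0:
            raise ValueError("offset must be positive")


def compute_default_offset(lognorm) -> float:
    """Half the minimum nonzero log-normalized value of the dataset."""
    if sp.issparse(lognorm):
        vals = lognorm.data
    else:
        vals = np.asarray(lognorm).ravel()
    nz = vals[vals > 0]
    if nz.size == 0:
        raise ValueError("no nonzero expression values")
    return float(nz.min() / 2.0)


def group_fold_change(expr_a, expr_b, spec: FoldChangeSpec = FoldChangeSpec()):
    """Fold change (group A over group B) of log-normalized expression.

    ``expr_a`` / ``expr_b`` are cells x genes arrays (or 1-D per-cell vectors
    for a single gene); means are taken over cells within each group.
    """
    a = np.atleast_2d(np.asarray(expr_a, dtype=float))
    b = np.atleast_2d(np.asarray(expr_b, dtype=float))
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both groups must be nonempty")
    mean_a = a.mean(axis=0)
    mean_b = b.mean(axis=0)
    fc = (np.expm1(mean_a) + spec.offset) / (np.expm1(mean_b) + spec.offset)
    return fc if fc.size > 1 else float(fc[0])


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumerating group assignments (handles ties)."""
    import itertools

    pooled = np.concatenate([x, y])
    n, n_a = len(pooled), len(x)
    ranks = rankdata(pooled)
    obs = ranks[:n_a].sum()
    mean = n_a * (n + 1) / 2.0
    stats = np.fromiter(
        (ranks[list(idx)].sum() for idx in itertools.combinations(range(n), n_a)),
        dtype=float,
    )
    return float(np.mean(np.abs(stats - mean) >= abs(obs - mean) - 1e-12))


def wilcoxon_rank_sum(x_a: np.ndarray, x_b: np.ndarray, exact_max_n: int = 12) -> np.ndarray:
    """Vectorized two-sided Wilcoxon rank-sum p-values per gene.

    ``x_a`` (n_a x genes) vs ``x_b`` (n_b x genes).  Normal approximation
    with tie correction and continuity correction; for small inputs (pooled
    size at most ``exact_max_n``) the exact permutation distribution of the
    rank sum is enumerated instead.  All-tied genes get p = 1.
    """
    x_a = np.atleast_2d(x_a)
    x_b = np.atleast_2d(x_b)
    n_a, n_b = x_a.shape[0], x_b.shape[0]
    n = n_a + n_b
    if n <= exact_max_n:
        return np.array(
            [
                1.0
                if np.all(x_a[:, j] == x_a[0, j]) and np.all(x_b[:, j] == x_a[0, j])
                else _exact_ranksum_p(x_a[:, j], x_b[:, j])
                for j in range(x_a.shape[1])
            ]
        )
    stacked = np.vstack([x_a, x_b])
    ranks = np.apply_along_axis(rankdata, 0, stacked)
    r_a = ranks[:n_a].sum(axis=0)
    u = r_a - n_a * (n_a + 1) / 2.0
    mu = n_a * n_b / 2.0

    # tie correction: sum t^3 - t over tied groups, per gene
    s = np.sort(stacked, axis=0)
    new_group = np.ones_like(s, dtype=bool)
    new_group[1:] = s[1:] != s[:-1]
    tie_term = np.empty(stacked.shape[1])
    for j in range(stacked.shape[1]):
        counts = np.diff(np.append(np.flatnonzero(new_group[:, j]), n))
        tie_term[j] = float(np.sum(counts**3 - counts))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))

    z = np.zeros_like(u)
    ok = var > 0
    diff = u - mu
    shrunk = np.sign(diff) * np.maximum(np.abs(diff) - 0.5, 0.0)  # continuity correction
    z[ok] = shrunk[ok] / np.sqrt(var[ok])
    p = np.where(ok, 2.0 * norm.sf(np.abs(z)), 1.0)
    return np.minimum(p, 1.0)


def within_patient_de(
    adata,
    labels: np.ndarray,
    sample_id: str,
    spec: FoldChangeSpec | None = None,
    gene_mask=None,
    layer: str = "lognorm",
) -> pd.DataFrame | None:
    """Abnormal-vs-normal DE table for one sample.

    Genes tested: those passing ``gene_mask`` (default: the DE analysis-gene
    selection, i.e. non-immunoglobulin) and expressed in at least one cell of
    the sample.  When ``spec`` is None the fold-change offset is recomputed
    from the sample's data (half the minimum nonzero log-normalized value).
    Returns None (with a logged warning) when either population is empty.
    """
    labels = np.asarray(labels)
    abn = labels == "abnormal"
    nrm = labels == "normal"
    if abn.sum() == 0 or nrm.sum() == 0:
        warnings.warn(f"sample {sample_id}: abnormal or normal population empty; skipped")
        return None
    mat = adata.layers[layer] if layer in adata.layers else adata.X
    dense = np.asarray(mat.todense()) if sp.issparse(mat) else np.asarray(mat)
    if spec is None:
        spec = FoldChangeSpec(offset=compute_default_offset(dense))
    if gene_mask is None:
        gene_mask = select_analysis_genes(adata.var, mode="de")
    expressed = (dense > 0).any(axis=0)
    test_mask = np.asarray(gene_mask, dtype=bool) & expressed
    genes = adata.var_names[test_mask]
    x_a = dense[np.ix_(abn, test_mask)]
    x_b = dense[np.ix_(nrm, test_mask)]

    p = wilcoxon_rank_sum(x_a, x_b)
    q = multipletests(p, method="fdr_bh")[1]
    fc = np.atleast_1d(group_fold_change(x_a, x_b, spec))
    lfc = np.log(fc)
    table = pd.DataFrame(
        {
            "gene": genes,
            "comparison": sample_id,
            "log_fold_change": lfc,
            "p_value": p,
            "q_value": q,
            "n_abnormal": int(abn.sum()),
            "n_normal": int(nrm.sum()),
        }
    )
    table["is_deg"] = (table["q_value"] < DEG_Q_THRESHOLD) & (
        table["log_fold_change"].abs() > DEG_LFC_THRESHOLD
    )
    return table


def prepare_pseudosample_tables(adata, labels: np.ndarray):
    """Pseudosample count matrix + design covariates for the cross-patient fit.

    Each sample is split into its abnormal and normal populations; counts
    are summed per pseudosample.  Genes are filtered with the CPM/cell-
    fraction/immunoglobulin rule.  Sample-level covariates (age with mean
    imputation of missing normal-donor ages, sex, batch, fresh/frozen) are
    emitted for an external model-fitting step.
    """
    labels = np.asarray(labels)
    X = sp.csr_matrix(adata.X)
    cols, col_meta = [], []
    abn_cells = labels == "abnormal"
    nrm_cells = labels == "normal"
    for sid in pd.unique(adata.obs["sample_id"]):
        in_s = (adata.obs["sample_id"] == sid).to_numpy()
        for pop, mask in (("abnormal", in_s & abn_cells), ("normal", in_s & nrm_cells)):
            if mask.sum() == 0:
                continue
            cols.append(np.asarray(X[mask].sum(axis=0)).ravel())
            meta = adata.obs.loc[mask].iloc[0]
            col_meta.append(
                {
                    "pseudosample": f"{sid}.{pop}",
                    "sample_id": sid,
                    "population": pop,
                    "n_cells": int(mask.sum()),
                    "stage": str(meta.get("stage", "NA")),
                    "age": float(meta.get("age", np.nan)),
                    "sex": str(meta.get("sex", "NA")),
                    "batch": str(meta.get("batch", "NA")),
                    "storage": str(meta.get("storage", "NA")),
                }
            )
    counts = pd.DataFrame(
        np.column_stack(cols) if cols else np.zeros((adata.n_vars, 0)),
        index=adata.var_names,
        columns=[m["pseudosample"] for m in col_meta],
    )
    design = pd.DataFrame(col_meta).set_index("pseudosample") if col_meta else pd.DataFrame()

    if len(design) and design["age"].isna().any():
        nbm = design["stage"] == "NBM"
        fill = design.loc[nbm, "age"].mean()
        if np.isnan(fill):
            fill = design["age"].mean()
        design["age"] = design["age"].fillna(fill)

    dense_nz = X > 0
    fa = (
        np.asarray(dense_nz[abn_cells].mean(axis=0)).ravel()
        if abn_cells.any()
        else np.zeros(adata.n_vars)
    )
    fn = (
        np.asarray(dense_nz[nrm_cells].mean(axis=0)).ravel()
        if nrm_cells.any()
        else np.zeros(adata.n_vars)
    )
    ig = adata.var["is_ig"].to_numpy(dtype=bool) if "is_ig" in adata.var else None
    keep = cpm_filter_genes(counts, fa, fn, ig_mask=ig) if counts.shape[1] else np.zeros(
        adata.n_vars, dtype=bool
    )
    return counts.loc[keep], design


def cross_patient_max_q(deg_tables: pd.DataFrame, n_patients_with_degs: int) -> pd.DataFrame:
    """Cross-patient roll-up of within-patient DEGs.

    For each gene and direction (up / down), over the patients where it was
    flagged: the maximum BH q multiplied by ``n_patients_with_degs`` (capped
    at 1), the maximum |log2 fold change|, and the number of patients
    detecting it.
    """
    if n_patients_with_degs < 1:
        raise ValueError("n_patients_with_degs must be >= 1")
    degs = deg_tables[deg_tables["is_deg"]].copy()
    if degs.empty:
        return pd.DataFrame(
            columns=["gene", "direction", "max_q_corrected", "max_abs_log2_fc", "n_patients"]
        )
    degs["direction"] = np.where(degs["log_fold_change"] > 0, "up", "down")
    degs["abs_log2_fc"] = degs["log_fold_change"].abs() / np.log(2)
    out = (
        degs.groupby(["gene", "direction"], observed=True)
        .agg(
            max_q=("q_value", "max"),
            max_abs_log2_fc=("abs_log2_fc", "max"),
            n_patients=("comparison", "nunique"),
        )
        .reset_index()
    )
    out["max_q_corrected"] = np.minimum(out["max_q"] * n_patients_with_degs, 1.0)
    return out[["gene", "direction", "max_q_corrected", "max_abs_log2_fc", "n_patients"]]
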