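"""Signature-activity statistics.

Operates on per-cell signature activities (the per-cell-normalized H matrix)
plus cell metadata: population means with bootstrap standard errors,
Kruskal-Wallis / Dunn group comparisons, the Jonckheere-Terpstra ordered
trend test, intratumor-heterogeneity flagging by coefficient of variation,
batch-association screening, and projection of a signature onto bulk
RNA-seq cohorts via median-of-ratios size factors and z-scored log
expression of the signature's top genes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kruskal, norm, pearsonr, rankdata, ranksums, spearmanr

__all__ = [
    "population_means",
    "group_activity_test",
    "dunn_test",
    "kruskal_wallis_p",
    "trend_test",
    "intratumor_heterogeneity",
    "batch_association_checks",
    "size_factors",
    "bulk_signature_activity",
]


# ---------------------------------------------------------------------------
# population means with bootstrap SEM
# ---------------------------------------------------------------------------


def population_means(
    activities: np.ndarray,
    sample_ids,
    populations,
    signature_names=None,
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean activity per (sample, population, signature) with bootstrap SEM.

    ``activities`` is cells x signatures; SEM is the SD of the means of
    ``n_boot`` bootstrap resamples of the population's cells (seeded, hence
    reproducible).  Empty populations are omitted.
    """
    A = np.atleast_2d(np.asarray(activities, dtype=float))
    sample_ids = np.asarray(sample_ids)
    populations = np.asarray(populations)
    K = A.shape[1]
    names = (
        list(signature_names) if signature_names is not None else [f"W{k + 1}" for k in range(K)]
    )
    rng = np.random.default_rng(seed)
    rows = []
    for sid in pd.unique(sample_ids):
        for pop in pd.unique(populations):
            mask = (sample_ids == sid) & (populations == pop)
            n = int(mask.sum())
            if n == 0:
                continue
            sub = A[mask]
            means = sub.mean(axis=0)
            idx = rng.integers(0, n, size=(n_boot, n))
            boot_means = sub[idx].mean(axis=1)  # n_boot x K
            sems = boot_means.std(axis=0)
            for k in range(K):
                rows.append(
                    {
                        "sample_id": sid,
                        "population": pop,
                        "signature": names[k],
                        "mean_activity": means[k],
                        "sem": sems[k],
                        "n_cells": n,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------


def _kw_statistic(ranks: np.ndarray, group_idx: list, n: int, tie_denom: float) -> float:
    h = 12.0 / (n * (n + 1)) * sum(
        ranks[idx].sum() ** 2 / len(idx) for idx in group_idx
    ) - 3.0 * (n + 1)
    return h / tie_denom if tie_denom > 0 else 0.0


def kruskal_wallis_p(groups, exact_max_n: int = 12) -> float:
    """Kruskal-Wallis p with tie correction; exact permutation enumeration
    for pooled sizes at most ``exact_max_n``, chi-square approximation above."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    sizes = [len(g) for g in groups]
    n = sum(sizes)
    pooled = np.concatenate(groups)
    ranks = rankdata(pooled)
    counts = pd.Series(pooled).value_counts().to_numpy()
    tie_denom = 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n) if n > 1 else 1.0
    bounds = np.cumsum([0] + sizes)
    obs_idx = [np.arange(bounds[i], bounds[i + 1]) for i in range(len(sizes))]
    h_obs = _kw_statistic(ranks, obs_idx, n, tie_denom)
    from math import comb, prod

    n_arrangements = prod(
        comb(int(np.cumsum(sizes)[i]), sizes[i]) for i in range(len(sizes))
    )
    if n > exact_max_n or n_arrangements > 100_000:
        return float(kruskal(*groups).pvalue)

    stats = []

    def rec(remaining, gi, parts):
        if gi == len(sizes) - 1:
            stats.append(_kw_statistic(ranks, parts + [np.array(remaining)], n, tie_denom))
            return
        for comb in itertools.combinations(remaining, sizes[gi]):
            rest = [x for x in remaining if x not in comb]
            rec(rest, gi + 1, parts + [np.array(comb)])

    rec(list(range(n)), 0, [])
    return float(np.mean(np.asarray(stats) >= h_obs - 1e-12))


def dunn_test(values, groups, comparisons="all") -> pd.DataFrame:
    """Dunn's post-hoc z-tests on pooled ranks with Bonferroni correction.

    ``comparisons``: "all" pairs, or a list of (group_a, group_b) pairs
    (e.g. every disease group against a reference).  The Bonferroni divisor
    is the number of comparisons actually performed.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = list(pd.unique(groups))
    ranks = rankdata(values)
    n = len(values)
    tie_counts = pd.Series(values).value_counts().to_numpy()
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1)) if n > 1 else 0.0
    mean_ranks = {g: ranks[groups == g].mean() for g in uniq}
    sizes = {g: int((groups == g).sum()) for g in uniq}

    pairs = (
        list(itertools.combinations(uniq, 2)) if comparisons == "all" else list(comparisons)
    )
    rows = []
    for ga, gb in pairs:
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[ga] + 1.0 / sizes[gb]))
        z = (mean_ranks[ga] - mean_ranks[gb]) / se if se > 0 else 0.0
        p = 2.0 * norm.sf(abs(z))
        rows.append({"group_a": ga, "group_b": gb, "z": z, "p_value": p})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(out["p_value"] * len(pairs), 1.0)
    return out


def group_activity_test(
    pop_means: pd.DataFrame,
    group_col: str = "group",
    value_col: str = "mean_activity",
    signature_col: str = "signature",
    fwer: float = 0.1,
    comparisons="all",
    min_group_size: int = 2,
) -> pd.DataFrame:
    """Per-signature Kruskal-Wallis omnibus + Dunn pairwise tests.

    ``pop_means`` holds one row per (sample, population, signature) with a
    group label (e.g. "NBM", "abnormal SMM").  Groups with fewer than
    ``min_group_size`` observations are excluded with a warning.  With only
    two groups the omnibus falls back to a rank-sum test.  Pairs significant
    at Bonferroni-corrected p < ``fwer`` are flagged.
    """
    rows = []
    for sig, tab in pop_means.groupby(signature_col, observed=True):
        counts = tab[group_col].value_counts()
        small = counts[counts < min_group_size].index
        if len(small):
            warnings.warn(f"{sig}: excluding groups with <{min_group_size} samples: {list(small)}")
            tab = tab[~tab[group_col].isin(small)]
        grps = list(pd.unique(tab[group_col]))
        if len(grps) < 2:
            continue
        samples = [tab.loc[tab[group_col] == g, value_col].to_numpy() for g in grps]
        if len(grps) == 2:
            kw_p = float(ranksums(samples[0], samples[1]).pvalue)
        else:
            kw_p = kruskal_wallis_p(samples)
        dunn = dunn_test(
            tab[value_col].to_numpy(),
            tab[group_col].to_numpy(),
            comparisons=comparisons if comparisons == "all" else [
                p for p in comparisons if p[0] in grps and p[1] in grps
            ],
        )
        for _, d in dunn.iterrows():
            rows.append(
                {
                    "signature": sig,
                    "kw_p": kw_p,
                    "group_a": d["group_a"],
                    "group_b": d["group_b"],
                    "dunn_p": d["p_value"],
                    "dunn_p_bonferroni": d["p_bonferroni"],
                    "significant": bool(d["p_bonferroni"] < fwer),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra ordered trend test
# ---------------------------------------------------------------------------


def _jt_statistic(samples: list[np.ndarray]) -> float:
    j = 0.0
    for i, j_ in itertools.combinations(range(len(samples)), 2):
        a, b = samples[i], samples[j_]
        j += float((a[:, None] < b[None, :]).sum()) + 0.5 * float(
            (a[:, None] == b[None, :]).sum()
        )
    return j


def trend_test(ordered_groups: list, exact_max_n: int = 12) -> float:
    """Two-sided Jonckheere-Terpstra test for a monotone trend across ordered groups.

    Sums pairwise Mann-Whitney counts over ordered group pairs.  Exact
    permutation enumeration when the pooled size is at most ``exact_max_n``;
    otherwise a normal approximation with continuity correction.
    """
    samples = [np.asarray(g, dtype=float) for g in ordered_groups]
    if len(samples) < 3:
        raise ValueError("need at least 3 ordered groups")
    sizes = [len(s) for s in samples]
    n = sum(sizes)
    j_obs = _jt_statistic(samples)
    mean_j = (n**2 - sum(s**2 for s in sizes)) / 4.0

    if n <= exact_max_n:
        pooled = np.concatenate(samples)
        # enumerate all distinct assignments of pooled values to the groups
        stats = []
        idx_all = list(range(n))

        def rec(remaining, gi, chosen):
            if gi == len(sizes) - 1:
                parts = chosen + [remaining]
                stats.append(_jt_statistic([pooled[list(p)] for p in parts]))
                return
            for comb in itertools.combinations(remaining, sizes[gi]):
                rest = [x for x in remaining if x not in comb]
                rec(rest, gi + 1, chosen + [list(comb)])

        rec(idx_all, 0, [])
        stats = np.asarray(stats)
        dev = abs(j_obs - mean_j)
        return float(np.mean(np.abs(stats - mean_j) >= dev - 1e-12))

    var_j = (
        n**2 * (2 * n + 3) - sum(s**2 * (2 * s + 3) for s in sizes)
    ) / 72.0
    if var_j <= 0:
        return 1.0
    dev = max(abs(j_obs - mean_j) - 0.5, 0.0)
    return float(2.0 * norm.sf(dev / np.sqrt(var_j)))


# ---------------------------------------------------------------------------
# intratumor heterogeneity
# ---------------------------------------------------------------------------


@dataclass
class HeterogeneityResult:
    cluster_means: pd.DataFrame  # signatures x clusters
    cv: pd.Series
    heterogeneous: pd.Series


def intratumor_heterogeneity(
    activities: np.ndarray,
    cluster_labels,
    signature_names=None,
    cv_threshold: float = 1.0,
) -> HeterogeneityResult:
    """Flag signatures whose per-cluster mean activity varies strongly within a tumor.

    ``activities`` is cells x signatures over one sample's abnormal cells;
    per signature, mu = vector of cluster means, CV = population SD(mu) /
    mean(mu); the signature is heterogeneous when CV exceeds the threshold.
    A single cluster leaves the CV undefined (flag False).
    """
    A = np.atleast_2d(np.asarray(activities, dtype=float))
    labels = np.asarray(cluster_labels)
    K = A.shape[1]
    names = (
        list(signature_names) if signature_names is not None else [f"W{k + 1}" for k in range(K)]
    )
    clusters = list(pd.unique(labels))
    mus = np.array([A[labels == cl].mean(axis=0) for cl in clusters]).T  # K x n_clusters
    cluster_means = pd.DataFrame(mus, index=names, columns=[str(c) for c in clusters])
    if len(clusters) < 2:
        warnings.warn("single cluster: CV undefined, no signature flagged")
        cv = pd.Series(np.nan, index=names, name="cv")
        flag = pd.Series(False, index=names, name="heterogeneous")
        return HeterogeneityResult(cluster_means, cv, flag)
    mean_mu = mus.mean(axis=1)
    sd_mu = mus.std(axis=1)  # population SD (divisor n)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv_vals = np.where(mean_mu > 0, sd_mu / mean_mu, np.nan)
    cv = pd.Series(cv_vals, index=names, name="cv")
    flag = pd.Series(
        np.where(np.isnan(cv_vals), False, cv_vals > cv_threshold), index=names
    ).astype(bool)
    flag.name = "heterogeneous"
    return HeterogeneityResult(cluster_means, cv, flag)


# ---------------------------------------------------------------------------
# batch-association screen
# ---------------------------------------------------------------------------


def batch_association_checks(
    activities: np.ndarray,
    sample_ids,
    sample_meta: pd.DataFrame,
    signature_names=None,
    covariates=(("sex", "binary"), ("storage", "binary"), ("batch", "categorical"), ("age", "continuous")),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen signature activities for batch-covariate associations.

    Activities should come from normal cells only (where no biological
    signal is expected).  Cells are aggregated to per-sample mean activity
    — cells within a sample share latent state, so sample means are the
    exchangeable units.  Binary covariates use a rank-sum test, categorical
    a Kruskal-Wallis test, continuous both Pearson and Spearman.
    """
    A = np.atleast_2d(np.asarray(activities, dtype=float))
    sample_ids = np.asarray(sample_ids)
    K = A.shape[1]
    names = (
        list(signature_names) if signature_names is not None else [f"W{k + 1}" for k in range(K)]
    )
    uniq = [s for s in pd.unique(sample_ids) if s in sample_meta.index]
    means = pd.DataFrame(
        [A[sample_ids == s].mean(axis=0) for s in uniq], index=uniq, columns=names
    )
    rows = []
    for cov, kind in covariates:
        if cov not in sample_meta.columns:
            continue
        cvals = sample_meta.loc[uniq, cov]
        if kind == "continuous":
            c = cvals.to_numpy(dtype=float)
            if np.nanstd(c) == 0:
                continue
            ok = ~np.isnan(c)
            for k, name in enumerate(names):
                a = means[name].to_numpy()[ok]
                rp, pp = pearsonr(a, c[ok]) if len(a) > 2 else (np.nan, np.nan)
                rs, ps = spearmanr(a, c[ok]) if len(a) > 2 else (np.nan, np.nan)
                rows.append(
                    {"signature": name, "covariate": cov, "test": "pearson", "stat": rp, "p_value": pp}
                )
                rows.append(
                    {"signature": name, "covariate": cov, "test": "spearman", "stat": rs, "p_value": ps}
                )
            continue
        levels = [lv for lv in pd.unique(cvals) if (cvals == lv).sum() >= 2]
        if len(levels) < 2:
            continue
        for k, name in enumerate(names):
            groups = [means.loc[cvals == lv, name].to_numpy() for lv in levels]
            if kind == "binary" or len(levels) == 2:
                res = ranksums(groups[0], groups[1])
                stat, p = float(res.statistic), float(res.pvalue)
                test = "ranksum"
            else:
                res = kruskal(*groups)
                stat, p = float(res.statistic), float(res.pvalue)
                test = "kruskal"
            rows.append(
                {"signature": name, "covariate": cov, "test": test, "stat": stat, "p_value": p}
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["flagged"] = out["p_value"] < alpha
    return out


# ---------------------------------------------------------------------------
# bulk projection
# ---------------------------------------------------------------------------


def size_factors(bulk_counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (genes x samples input).

    Per sample: the median over genes (with a nonzero geometric mean) of the
    ratio of the sample's count to the gene's geometric mean across samples.
    """
    counts = bulk_counts.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 bulk samples")
    with np.errstate(divide="ignore"):
        log_gm = np.log(counts).mean(axis=1)
    usable = np.isfinite(log_gm)
    if not usable.any():
        raise ValueError("no gene has nonzero counts in every sample")
    ratios = counts[usable] / np.exp(log_gm[usable])[:, None]
    return pd.Series(np.median(ratios, axis=0), index=bulk_counts.columns, name="size_factor")


def bulk_signature_activity(bulk_counts: pd.DataFrame, top_genes) -> pd.Series:
    """Signature activity per bulk sample: mean z-scored log expression of top genes.

    Counts are size-factor normalized, scaled to per-million, log1p-
    transformed; each gene is z-scored across samples (zero-variance genes
    contribute 0 with a warning); the activity is the mean z over the
    signature's gene list.
    """
    top_genes = [g for g in top_genes if g in bulk_counts.index]
    if not top_genes:
        raise ValueError("none of the signature genes are present in the bulk matrix")
    sf = size_factors(bulk_counts)
    normed = bulk_counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    per_million = normed / normed.sum(axis=0, keepdims=True) * 1e6
    log_expr = pd.DataFrame(
        np.log1p(per_million), index=bulk_counts.index, columns=bulk_counts.columns
    )
    sub = log_expr.loc[top_genes]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} zero-variance genes contribute z=0")
    z = sub.sub(mu, axis=0).div(sd.replace(0, np.inf), axis=0)
    return z.mean(axis=0).rename("bulk_signature_activity")
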