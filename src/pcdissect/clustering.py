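"""Pluggable community-detection backend for per-sample cluster labels.

Cluster labels are consumed, not contributed, by the analyses in this
package (cell labeling, intratumor heterogeneity), so the backend is a thin
wrapper over standard routines: scanpy highly-variable-gene selection,
scaling, PCA, neighborhood graph and Leiden — or a KMeans fallback on the
same PCA embedding.  Immunoglobulin genes are excluded before clustering.
"""

from __future__ import annotations

import warnings

import numpy as np

from .preprocessing import select_analysis_genes

__all__ = ["cluster_cells"]


def cluster_cells(
    adata,
    method: str = "leiden",
    min_disp: float = 0.6,
    n_pcs: int = 10,
    n_neighbors: int = 15,
    resolution: float = 0.6,
    n_clusters: int = 4,
    random_state: int = 0,
    layer: str = "lognorm",
) -> np.ndarray:
    """Cluster the cells of one sample; returns per-cell string labels."""
    import scanpy as sc

    if adata.n_obs < 3:
        return np.zeros(adata.n_obs, dtype=int).astype(str)

    sub = adata.copy()
    sub.X = sub.layers[layer].copy() if layer in sub.layers else sub.X
    keep = select_analysis_genes(sub.var, mode="clustering")
    sub = sub[:, keep].copy()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(sub, min_disp=min_disp, flavor="seurat")
        if sub.var["highly_variable"].sum() >= 5:
            sub = sub[:, sub.var["highly_variable"]].copy()
        sc.pp.scale(sub, max_value=10)
        n_comp = int(min(n_pcs, sub.n_obs - 1, sub.n_vars - 1))
        n_comp = max(n_comp, 1)
        sc.pp.pca(sub, n_comps=n_comp, svd_solver="arpack", random_state=random_state)
        if method == "kmeans":
            from sklearn.cluster import KMeans

            k = int(min(n_clusters, sub.n_obs))
            lab = KMeans(n_clusters=k, n_init=10, random_state=random_state).fit_predict(
                sub.obsm["X_pca"]
            )
            return lab.astype(str)
        sc.pp.neighbors(
            sub,
            n_neighbors=int(min(n_neighbors, max(sub.n_obs - 1, 2))),
            n_pcs=n_comp,
            random_state=random_state,
        )
        sc.tl.leiden(
            sub,
            resolution=resolution,
            random_state=random_state,
            flavor="igraph",
            n_iterations=2,
            directed=False,
        )
    return sub.obs["leiden"].to_numpy().astype(str)
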