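# pcdissect

In silico dissection of CD138+ plasma-cell samples from single-cell RNA-seq,
for studying multiple myeloma and its precursor conditions (MGUS and
smoldering myeloma). At precursor stages a bone-marrow biopsy contains a
mixture of normal plasma cells and the emerging tumor clone; bulk assays
average over the mixture, so characterizing the early tumor requires
separating the two populations cell by cell. `pcdissect` implements that
separation and the analyses built on it:

* **Bayesian tumor-purity model.** A clonal plasma-cell population expresses
  exclusively kappa or exclusively lambda immunoglobulin light chain, while
  normal plasma cells mix both. With `N` chain-assigned cells of which
  `n_κ` are kappa, the model

      κ_n ~ TruncNormal(μ, σ², 0, 1)   (normal-cell kappa fraction)
      κ_t ~ Bernoulli(0.5)             (clonal chain)
      ρ   ~ Beta(1, 1)                 (sample purity)
      n_κ ~ Binomial(N, ρ·κ_t + (1−ρ)·κ_n)

  yields a posterior over purity ρ on a 100-point grid, reported as mode and
  95% interval. The prior (μ, σ) is estimated from healthy-donor samples.
* **Automated cell labeling.** Per-sample clustering (pluggable
  Leiden/KMeans backend) plus light-chain and driver-gene rules label each
  cell normal or abnormal; the labeled purity carries a conjugate
  Beta(n+1, N−n+1) interval and is cross-checked against the Bayesian
  estimate.
* **Within-patient differential expression.** Wilcoxon rank-sum tests (exact
  enumeration at small n) of a patient's abnormal vs own normal cells,
  Benjamini–Hochberg correction per patient, and a fold-change statistic
  `(exp(mean log-normalized) − 1 + offset)` per group with a data-derived
  offset; DEGs at q < 0.1 and |log FC| > log 1.5, with a max-q cross-patient
  roll-up.
* **ARD-NMF gene signatures.** Automatic-relevance-determination NMF
  (Poisson likelihood, exponential prior on W, half-normal prior on H) that
  discovers the number of expression programs, with restarts, a 20% cell
  holdout for model selection, signature classification (patient-specific /
  single-gene / interpretable) and specificity-weighted gene ranking —
  exposed as a scikit-learn style estimator (`ARDNMF`).
* **Signature statistics.** Bootstrap standard errors, Kruskal–Wallis +
  Dunn group tests, the Jonckheere–Terpstra ordered trend test, intratumor
  heterogeneity (coefficient of variation of per-cluster mean activity > 1),
  batch-association screening, and projection of a signature onto bulk
  RNA-seq cohorts via median-of-ratios size factors.
* **Synthetic cohorts.** A generator producing 10x-style UMI matrices of
  normal/abnormal mixtures with known purity, clonal chain, latent
  signatures, planted fold changes and subclonal structure — the ground
  truth that every analysis above is tested against.

## Worked example

```python
import numpy as np
from pcdissect.simulate import SimulationConfig, generate_cohort
from pcdissect.preprocessing import log_normalize, qc_filter_cells
from pcdissect.purity import (LightChainPurityModel, assign_light_chain,
                              summarize_light_chains)

cfg = SimulationConfig(seed=1)          # 12 samples across NBM/MGUS/SMM/MM
adata, truth = generate_cohort(cfg)
adata = log_normalize(qc_filter_cells(adata))
chains = assign_light_chain(adata)       # kappa / lambda / unassigned per cell
summ = summarize_light_chains(chains, adata.obs["sample_id"].to_numpy())

nbm = [s for s in summ.index if s.startswith("NBM")]
model = LightChainPurityModel().fit((summ.loc[nbm, "n_kappa"] / summ.loc[nbm, "N"]).to_numpy())
for sid in ["NBM-1", "MGUS-1", "SMM-1", "MM-1"]:
    post = model.posterior(int(summ.loc[sid, "n_kappa"]), int(summ.loc[sid, "N"]))
    print(f"{sid}: purity mode={post.mode:.3f} "
          f"CI=({post.ci95[0]:.3f}, {post.ci95[1]:.3f}) truth={truth.true_purity[sid]:.3f}")
```

Output:

```
NBM-1: purity mode=0.000 CI=(0.000, 0.377) truth=0.000
MGUS-1: purity mode=0.737 CI=(0.509, 0.834) truth=0.710
SMM-1: purity mode=0.606 CI=(0.297, 0.739) truth=0.688
MM-1: purity mode=0.970 CI=(0.892, 0.984) truth=0.987
```

Each line shows the posterior-mode tumor purity of one synthetic sample with
its 95% interval against the generating truth: the healthy-donor sample is
called pure normal, the precursor samples are mixtures, and the overt
myeloma sample is nearly pure tumor.

The same analyses run as a pipeline from the shell:

```bash
pcdissect --workdir run --seed 1 simulate
pcdissect --workdir run --seed 1 qc
# ... normalize, purity, label, de, nmf, sigstats, report
```

`report` collates the two purity estimates per sample, DEG tables, the
signature catalog and heterogeneity flags into `report/report.json`.

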