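"""Synthetic plasma-cell cohort generator.

Emulates the data structure assumed by the purity / differential-expression /
signature analyses in this package: each sample is a mixture of normal and
abnormal (clonal) CD138+ plasma cells.  Normal cells express kappa light chain
with a per-sample probability drawn from a truncated normal on [0, 1];
abnormal cells all carry the sample's clonal chain (kappa or lambda).  UMI
counts are Poisson around a low-rank rate ``library * (W @ theta)`` built
from ``k_true`` latent nonnegative gene signatures, with a dedicated
high-mean light-chain component on IGKC / IGLC2 and optional planted
fold-change effects on abnormal cells.

The generator is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import truncnorm

__all__ = [
    "PlantedDEG",
    "SimulationConfig",
    "GroundTruth",
    "sample_truncated_normal",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "NORMAL_SIGNATURE_MARKERS",
]

#: marker genes anchoring the "normal plasma cell" latent signature
NORMAL_SIGNATURE_MARKERS = ("CD27", "CD79A", "TXNIP", "JSRP1", "CTSH", "HCST", "RNU12", "SAT1")

_IG_EXTRA = ("IGHM", "IGHG1", "IGHA1", "IGLC3", "IGKV1-5")
_SEX_GENES = ("XIST", "RPS4Y1")
_N_MITO = 8

_STAGES = ("NBM", "MGUS", "SMM", "MM")


@dataclass(frozen=True)
class PlantedDEG:
    """One planted differential-expression effect.

    ``n_genes`` target genes get their Poisson rate multiplied by
    ``fold_change`` (direction="up") or divided by it (direction="down") in
    the ``population`` cells ("abnormal" or "normal") of every non-NBM sample.
    """

    n_genes: int = 25
    fold_change: float = 2.0
    direction: str = "up"
    population: str = "abnormal"

    def __post_init__(self):
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if self.population not in ("abnormal", "normal"):
            raise ValueError("population must be 'abnormal' or 'normal'")


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults emulate a desk-scale version of a precursor-myeloma cohort:
    four disease stages, per-stage purity ranges matching the observed
    spread (NBM pure normal; MGUS 0-0.81; SMM 0.58-1; MM 0.98-1), and a
    normal-cell kappa fraction centred at 0.6 (the physiological ~60:40
    kappa:lambda ratio) with SD 0.05 across donors.
    """

    n_samples_per_stage: Mapping[str, int] = field(
        default_factory=lambda: {"NBM": 4, "MGUS": 2, "SMM": 4, "MM": 2}
    )
    cells_per_sample: tuple[int, int] = (120, 200)
    n_genes: int = 500
    k_true: int = 5
    kappa_prior_mu: float = 0.6
    kappa_prior_sigma: float = 0.05
    purity_by_stage: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "NBM": (0.0, 0.0),
            "MGUS": (0.0, 0.81),
            "SMM": (0.58, 1.0),
            "MM": (0.98, 1.0),
        }
    )
    #: optional explicit per-sample purity (overrides purity_by_stage)
    purity_per_sample: Sequence[float] | None = None
    #: optional explicit per-sample clonal chain ("kappa"/"lambda");
    #: default Bernoulli(0.5) per sample
    clonal_chain_per_sample: Sequence[str] | None = None
    planted_degs: Sequence[PlantedDEG] = field(
        default_factory=lambda: (
            PlantedDEG(25, 2.0, "up", "abnormal"),
            PlantedDEG(25, 2.0, "down", "abnormal"),
        )
    )
    #: share of a cell's library produced by its clonal/assigned light-chain
    #: gene; ~0.35 mirrors the immunoglobulin dominance of real plasma cells
    light_chain_fraction: float = 0.35
    #: log-normal per-cell library size (natural-log mean and SD)
    library_log_mean: float = 7.3
    library_log_sigma: float = 0.3
    #: Dirichlet concentration of per-cell signature exposures around the
    #: population mixture
    exposure_concentration: float = 50.0
    #: number of abnormal subclones per sample; >1 plants signature
    #: heterogeneity (each extra subclone over-expresses a private signature)
    n_subclones: int = 1
    #: weight of the private signature inside a private subclone's mixture
    private_signature_weight: float = 0.7
    #: abnormal cells reuse the normal-cell signature mixture; the planted
    #: effects (and the clonal light chain) are then the only systematic
    #: population difference — the condition for DE calibration experiments
    share_population_mixture: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.kappa_prior_mu < 1:
            raise ValueError("kappa_prior_mu must be in (0, 1)")
        if self.kappa_prior_sigma <= 0:
            raise ValueError("kappa_prior_sigma must be positive")
        if self.k_true > self.n_genes:
            raise ValueError("k_true cannot exceed n_genes")
        if self.k_true < 1 or self.n_genes < 1:
            raise ValueError("k_true and n_genes must be positive")
        if not 0 <= self.light_chain_fraction < 1:
            raise ValueError("light_chain_fraction must be in [0, 1)")
        lo, hi = self.cells_per_sample
        if lo < 0 or hi < lo:
            raise ValueError("cells_per_sample must be a nondecreasing pair of nonnegative ints")
        if self.n_subclones > 1 and self.n_subclones > self.k_true:
            raise ValueError("need k_true >= n_subclones to grant each subclone a private signature")
        n_samples = sum(self.n_samples_per_stage.values())
        if self.purity_per_sample is not None:
            if len(self.purity_per_sample) != n_samples:
                raise ValueError("purity_per_sample length must match total sample count")
            if any(not 0 <= p <= 1 for p in self.purity_per_sample):
                raise ValueError("purities must be in [0, 1]")
        if self.clonal_chain_per_sample is not None:
            if len(self.clonal_chain_per_sample) != n_samples:
                raise ValueError("clonal_chain_per_sample length must match total sample count")
            if any(c not in ("kappa", "lambda") for c in self.clonal_chain_per_sample):
                raise ValueError("clonal chains must be 'kappa' or 'lambda'")


@dataclass
class GroundTruth:
    """Truth record of a generated cohort, for recovery tests."""

    true_purity: dict[str, float]
    clonal_chain: dict[str, str]
    kappa_n: dict[str, float]
    true_W: np.ndarray  # genes x k_true, columns sum to 1
    true_H: np.ndarray  # k_true x cells (library-scaled exposures)
    planted_degs: list[dict]
    cluster_of_cell: np.ndarray  # per-cell subclone/population label


def sample_truncated_normal(mu: float, sigma: float, size, rng: np.random.Generator) -> np.ndarray:
    """Draw from Normal(mu, sigma^2) truncated to [0, 1] by inverse CDF (exact, no rejection)."""
    a, b = (0.0 - mu) / sigma, (1.0 - mu) / sigma
    u = rng.random(size)
    return truncnorm.ppf(u, a, b, loc=mu, scale=sigma)


def _build_gene_table(n_genes: int) -> pd.DataFrame:
    special = ["IGKC", "IGLC2", *_IG_EXTRA]
    special += [f"MT-GENE{i}" for i in range(1, _N_MITO + 1)]
    special += list(_SEX_GENES)
    special += list(NORMAL_SIGNATURE_MARKERS)
    if n_genes < len(special):
        raise ValueError(f"n_genes must be at least {len(special)}")
    symbols = special + [f"GENE{i:04d}" for i in range(n_genes - len(special))]
    df = pd.DataFrame(index=pd.Index(symbols, name="symbol"))
    df["gene_id"] = [f"SYN{i:05d}" for i in range(n_genes)]
    df["is_ig"] = [s.startswith(("IGH", "IGK", "IGL")) for s in symbols]
    df["is_mito"] = [s.startswith("MT-") for s in symbols]
    role = np.array(["none"] * n_genes, dtype=object)
    role[symbols.index("IGKC")] = "IGKC"
    role[symbols.index("IGLC2")] = "IGLC2"
    df["light_chain_role"] = role
    return df


def generate_cohort(config: SimulationConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Generate a cohort of single-cell UMI matrices with known ground truth.

    Returns an AnnData (cells x genes, sparse integer counts, per-cell
    metadata in ``.obs``, gene annotations in ``.var``) and the matching
    :class:`GroundTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _build_gene_table(config.n_genes)
    G, K = config.n_genes, config.k_true
    symbols = list(genes.index)

    # --- latent signatures -------------------------------------------------
    W = rng.gamma(0.5, 1.0, size=(G, K))
    ig_rows = genes["is_ig"].to_numpy()
    W[ig_rows, :] *= 0.02  # IG loci carried by the dedicated light-chain component
    # signature 0 is the "normal plasma cell" program anchored on marker genes
    marker_idx = [symbols.index(m) for m in NORMAL_SIGNATURE_MARKERS]
    W[marker_idx, 0] = W[marker_idx, 0] * 5.0 + 25.0
    if K > 1:
        W[marker_idx, 1:] *= 0.05
    W /= W.sum(axis=0, keepdims=True)

    # --- planted DEG gene sets --------------------------------------------
    overall = W.mean(axis=1)
    order = np.argsort(overall)
    protected = set(marker_idx) | set(np.flatnonzero(ig_rows)) | set(
        np.flatnonzero(genes["is_mito"].to_numpy())
    ) | {symbols.index(s) for s in _SEX_GENES}
    mid = [g for g in order[G // 4: 3 * G // 4][::-1] if g not in protected]
    planted: list[dict] = []
    cursor = 0
    for spec_ in config.planted_degs:
        idx = np.array(mid[cursor: cursor + spec_.n_genes], dtype=int)
        cursor += spec_.n_genes
        if len(idx) < spec_.n_genes:
            raise ValueError("not enough non-special genes to plant all DEG sets")
        # signature-neutral baseline: identical weight across signatures so
        # the planted multiplier is the only systematic group difference
        W[idx, :] = W[idx, :].mean(axis=1, keepdims=True)
        planted.append(
            {
                "genes": idx,
                "symbols": [symbols[g] for g in idx],
                "fold_change": spec_.fold_change,
                "direction": spec_.direction,
                "population": spec_.population,
            }
        )

    # --- per-sample structure ----------------------------------------------
    sample_ids, stages = [], []
    for stage in _STAGES:
        for i in range(config.n_samples_per_stage.get(stage, 0)):
            sample_ids.append(f"{stage}-{i + 1}")
            stages.append(stage)
    n_samples = len(sample_ids)

    if config.purity_per_sample is not None:
        purities = np.asarray(config.purity_per_sample, dtype=float)
    else:
        purities = np.array(
            [rng.uniform(*config.purity_by_stage[s]) for s in stages]
        )
    if config.clonal_chain_per_sample is not None:
        chains = list(config.clonal_chain_per_sample)
    else:
        chains = ["kappa" if rng.random() < 0.5 else "lambda" for _ in range(n_samples)]
    kappa_n = sample_truncated_normal(
        config.kappa_prior_mu, config.kappa_prior_sigma, n_samples, rng
    )

    # population-level exposure mixtures
    normal_mix = np.zeros(K)
    normal_mix[0] = 0.75
    if K > 1:
        rest = rng.dirichlet(np.full(K - 1, 2.0))
        normal_mix[1:] = 0.25 * rest
    else:
        normal_mix[0] = 1.0

    kc, lc = symbols.index("IGKC"), symbols.index("IGLC2")
    lcf = config.light_chain_fraction

    X_blocks, obs_rows = [], []
    truth_purity, truth_chain, truth_kn = {}, {}, {}
    H_cols, cluster_labels = [], []
    sexes = ["F" if i % 2 == 0 else "M" for i in range(n_samples)]
    batches = [f"batch{1 + (i % 2)}" for i in range(n_samples)]
    storage = ["fresh" if i % 2 == 0 else "frozen" for i in range(n_samples)]
    ages = [45.0 + 2.0 * i for i in range(n_samples)]
    if stages.count("NBM"):
        ages[stages.index("NBM")] = np.nan  # one donor with missing age (exercises imputation)

    for si, (sid, stage) in enumerate(zip(sample_ids, stages)):
        n_cells = int(rng.integers(config.cells_per_sample[0], config.cells_per_sample[1] + 1))
        rho = float(purities[si])
        is_abn = rng.random(n_cells) < rho
        chain = np.where(
            is_abn,
            chains[si],
            np.where(rng.random(n_cells) < kappa_n[si], "kappa", "lambda"),
        )

        # abnormal mixture: weak on the normal program, sample-specific otherwise
        if config.share_population_mixture:
            abn_mix = normal_mix.copy()
        elif K > 1:
            abn_mix = np.zeros(K)
            abn_mix[0] = 0.05
            abn_mix[1:] = 0.95 * rng.dirichlet(np.full(K - 1, 1.5))
        else:
            abn_mix = normal_mix.copy()

        # subclones: each extra subclone expresses a private signature that no
        # other cell of the sample touches
        n_sub = max(1, config.n_subclones)
        privates: list[int] = []
        if n_sub > 1 and K > 2:
            avail = list(range(1, K))
            privates = [avail[(si + j) % len(avail)] for j in range(n_sub - 1)]
        base = abn_mix.copy()
        if privates:
            base[privates] = 0.0
            base /= base.sum()
        sub_mixes = [base]
        for p in privates:
            m = base * (1.0 - config.private_signature_weight)
            m[p] = config.private_signature_weight
            sub_mixes.append(m / m.sum())
        subclone = np.where(is_abn, rng.integers(0, n_sub, n_cells), -1)

        conc = config.exposure_concentration
        theta = np.empty((n_cells, K))
        for c in range(n_cells):
            mix = normal_mix if not is_abn[c] else sub_mixes[subclone[c]]
            theta[c] = rng.dirichlet(np.maximum(mix, 1e-6) * conc) if K > 1 else [1.0]

        lib = rng.lognormal(config.library_log_mean, config.library_log_sigma, n_cells)
        rate = (theta @ W.T) * (lib * (1.0 - lcf))[:, None]

        for p in planted:
            if stage == "NBM":
                continue
            mask = is_abn if p["population"] == "abnormal" else ~is_abn
            f = p["fold_change"] if p["direction"] == "up" else 1.0 / p["fold_change"]
            rate[np.ix_(mask, p["genes"])] *= f

        # dedicated light-chain component: strongly elevated counts on the
        # assigned chain's constant gene
        rate[chain == "kappa", kc] += lib[chain == "kappa"] * lcf
        rate[chain == "lambda", lc] += lib[chain == "lambda"] * lcf

        counts = rng.poisson(rate)
        X_blocks.append(sp.csr_matrix(counts))
        H_cols.append((theta * (lib * (1.0 - lcf))[:, None]).T)
        lab = np.where(is_abn, [f"{sid}/subclone{j}" for j in subclone], f"{sid}/normal")
        cluster_labels.append(lab)

        truth_purity[sid] = rho
        truth_chain[sid] = chains[si]
        truth_kn[sid] = float(kappa_n[si])
        for c in range(n_cells):
            obs_rows.append(
                {
                    "barcode": f"{sid}_CELL{c:05d}",
                    "sample_id": sid,
                    "stage": stage,
                    "sex": sexes[si],
                    "age": ages[si],
                    "batch": batches[si],
                    "storage": storage[si],
                    "is_abnormal_true": bool(is_abn[c]),
                    "chain_true": chain[c],
                }
            )

    X = sp.vstack(X_blocks, format="csr") if X_blocks else sp.csr_matrix((0, G))
    obs = pd.DataFrame(obs_rows).set_index("barcode") if obs_rows else pd.DataFrame(
        index=pd.Index([], name="barcode")
    )
    adata = ad.AnnData(X=X, obs=obs, var=genes.copy())
    adata.obs["stage"] = pd.Categorical(adata.obs.get("stage", []), categories=_STAGES)

    truth = GroundTruth(
        true_purity=truth_purity,
        clonal_chain=truth_chain,
        kappa_n=truth_kn,
        true_W=W,
        true_H=np.hstack(H_cols) if H_cols else np.zeros((K, 0)),
        planted_degs=planted,
        cluster_of_cell=np.concatenate(cluster_labels) if cluster_labels else np.array([]),
    )
    return adata, truth


# ---------------------------------------------------------------------------
# 10x cellranger-style on-disk layout: MTX + genes/barcodes TSV + cell metadata
# ---------------------------------------------------------------------------

def write_cohort(adata: ad.AnnData, path) -> None:
    """Write a cohort as MatrixMarket (genes x cells, integer) with TSV sidecars."""
    from pathlib import Path
    from scipy.io import mmwrite

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(adata.X.T)  # genes x cells, 10x orientation
    mmwrite(path / "matrix.mtx", mat, field="integer")
    genes = adata.var.reset_index()
    first = genes.columns[0]
    cols = [c for c in ["gene_id", first, "is_ig", "is_mito", "light_chain_role"] if c in genes]
    genes[cols].rename(columns={first: "symbol"}).to_csv(
        path / "genes.tsv", sep="\t", index=False
    )
    pd.Series(adata.obs_names, name="barcode").to_csv(
        path / "barcodes.tsv", sep="\t", index=False, header=False
    )
    adata.obs.to_csv(path / "cell_meta.tsv", sep="\t")


def read_cohort(path) -> ad.AnnData:
    """Read a cohort written by :func:`write_cohort`."""
    from pathlib import Path
    from scipy.io import mmread

    path = Path(path)
    X = sp.csr_matrix(mmread(path / "matrix.mtx").T)
    genes = pd.read_csv(path / "genes.tsv", sep="\t").set_index("symbol")
    try:
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    except pd.errors.EmptyDataError:
        barcodes = pd.Series([], dtype=str)
    meta = pd.read_csv(path / "cell_meta.tsv", sep="\t", index_col=0)
    if len(meta) != len(barcodes):
        raise ValueError("cell metadata does not match barcode count")
    meta.index = pd.Index(barcodes.values, name="barcode")
    if X.shape[0] != len(barcodes) or X.shape[1] != len(genes):
        # a 0-cell matrix round-trips as shape (0, G)
        if len(barcodes) == 0 and X.shape[0] == len(genes):
            X = sp.csr_matrix((0, len(genes)))
        else:
            raise ValueError("matrix dimensions do not match metadata")
    adata = ad.AnnData(X=X.astype(np.int64), obs=meta, var=genes)
    return adata
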