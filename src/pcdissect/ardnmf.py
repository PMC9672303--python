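"""Automatic-relevance-determination NMF with a Poisson likelihood.

MAP estimation of V ~ Poisson(WH) with an exponential (L1) prior on the
columns of W, a half-normal (L2) prior on the rows of H, and per-component
relevance weights lambda_k with inverse-gamma-style hyperparameters (a, b).
The negative log-posterior minimized is

    D_KL(V | WH)
    + sum_k (1/lambda_k) * (sum_g w_gk + sum_c h_kc^2 / 2 + b)
    + (G + C/2 + a + 1) * sum_k log(lambda_k)

up to an additive constant in (a, b).  Components whose relevance collapses
to the prior floor b / (G + C/2 + a + 1) are pruned after convergence,
discovering the effective rank automatically.

Updates are majorization-minimization steps, so the objective is
monotonically non-increasing:

* W: the standard multiplicative KL update with the +1/lambda_k L1 term in
  the denominator.
* H: the exact minimizer of the KL majorizer plus the quadratic prior — the
  positive root of a per-entry quadratic (a heuristic power update is not
  guaranteed monotone here).
* lambda: its closed-form stationary point given W and H.

The sklearn-style :class:`ARDNMF` estimator wraps restarts, an 80/20 cell
holdout, and modal-rank solution selection; post-processing helpers
(factor normalization, per-cell activity scaling, signature classification
and specificity-weighted gene ranking) operate on the resulting factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ArdNmfConfig",
    "FactorizationResult",
    "SignatureCatalog",
    "compute_b",
    "fit_ardnmf",
    "fit_restarts",
    "project_holdout",
    "select_solution",
    "normalize_factors",
    "normalize_activities_per_cell",
    "classify_signatures",
    "specificity_scores",
    "rank_genes",
    "ARDNMF",
]

_EPS = 1e-10


@dataclass
class ArdNmfConfig:
    """Hyperparameters of a single ARD-NMF fit / restart schedule."""

    K_init: int = 50
    max_iter: int = 7000
    tol: float = 1e-5
    a: float = 10.0
    b: float | None = None  # computed from a and mean(V) unless overridden
    n_restarts: int = 100
    holdout_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.a <= 2:
            raise ValueError("a must exceed 2 so that b is real")
        if not 0 <= self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in [0, 1)")


@dataclass
class FactorizationResult:
    W: np.ndarray  # genes x K
    H: np.ndarray  # K x cells
    lam: np.ndarray  # K relevance weights
    K_final: int
    objective_trace: np.ndarray
    heldout_divergence: float = np.nan
    converged: bool = True
    seed: int | None = None
    n_iter: int = 0


@dataclass
class SignatureCatalog:
    classes: pd.Series  # per-signature: patient_specific / single_gene / interpretable
    specificity: np.ndarray  # genes x K
    importance: np.ndarray  # genes x K (= W * specificity)
    top_genes: dict = field(default_factory=dict)


def compute_b(a: float, V, K_init: int) -> float:
    """Scale hyperparameter b from a and the data mean: sqrt((a-1)(a-2) mean(V) / K)."""
    if a <= 2:
        raise ValueError("a must exceed 2")
    mean_v = float(V.mean())
    if mean_v <= 0:
        raise ValueError("degenerate all-zero matrix: mean(V) must be positive")
    return float(np.sqrt((a - 1.0) * (a - 2.0) * mean_v / K_init))


def _kl_div(V: np.ndarray, Vhat: np.ndarray) -> float:
    Vhat = np.maximum(Vhat, _EPS)
    pos = V > 0
    return float(np.sum(V[pos] * np.log(V[pos] / Vhat[pos])) - V.sum() + Vhat.sum())


def _objective(V, W, H, lam, b, coef) -> float:
    pen = np.sum((W.sum(axis=0) + 0.5 * (H**2).sum(axis=1) + b) / lam)
    return _kl_div(V, W @ H) + pen + coef * np.sum(np.log(lam))


def _fit_single(
    V: np.ndarray,
    K_init: int,
    a: float,
    b: float,
    max_iter: int,
    tol: float,
    rng: np.random.Generator,
) -> FactorizationResult:
    G, C = V.shape
    coef = G + C / 2.0 + a + 1.0
    lam_floor = b / coef
    scale = np.sqrt(max(V.mean(), _EPS) / K_init)
    W = rng.random((G, K_init)) * 2.0 * scale + _EPS
    H = rng.random((K_init, C)) * 2.0 * scale + _EPS
    lam = (W.sum(axis=0) + 0.5 * (H**2).sum(axis=1) + b) / coef

    # constant pieces of D_KL(V|WH): only sum(v * log vhat) and sum(vhat)
    # change across iterations; the nonzero structure of V is fixed
    nz = np.flatnonzero(V.ravel() > 0)
    v_nz = V.ravel()[nz]
    kl_const = float(np.sum(v_nz * np.log(v_nz)) - V.sum())

    # contribution of already-pruned (dead) components to the objective; kept
    # in the reported trace so it stays comparable and monotone across prunes
    pruned_const = 0.0
    trace = np.empty(max_iter)
    converged = False
    it = 0
    Vhat = np.maximum(W @ H, _EPS)
    for it in range(max_iter):
        # W update (KL + exponential prior): multiplicative
        numW = (V / Vhat) @ H.T
        denW = H.sum(axis=1)[None, :] + 1.0 / lam[None, :]
        W *= numW / np.maximum(denW, _EPS)
        W = np.maximum(W, _EPS)

        # H update (KL + half-normal prior): positive root of
        # h^2/lambda + A h - B h_old = 0 per entry (exact majorizer minimum)
        Vhat = np.maximum(W @ H, _EPS)
        B = W.T @ (V / Vhat) * H  # numerator term times h_old
        A = W.sum(axis=0)[:, None]
        inv_lam = (1.0 / lam)[:, None]
        H = (np.sqrt(A**2 + 4.0 * inv_lam * B) - A) / (2.0 * inv_lam)
        H = np.maximum(H, _EPS)

        w_mass = W.sum(axis=0)
        h_sq = 0.5 * (H**2).sum(axis=1)
        lam_new = (w_mass + h_sq + b) / coef
        rel = np.linalg.norm(lam_new - lam[: len(lam_new)]) / max(np.linalg.norm(lam), _EPS)
        lam = lam_new

        Vhat = np.maximum(W @ H, _EPS)  # current state; reused by next W update
        kl = kl_const - float(v_nz @ np.log(np.take(Vhat.ravel(), nz))) + float(Vhat.sum())
        pen = float(np.sum((w_mass + h_sq + b) / lam)) + coef * float(np.sum(np.log(lam)))
        trace[it] = kl + pen + pruned_const

        # active pruning: components at the relevance floor whose factors
        # have decayed to numerical zero; their (constant) objective share is
        # folded into pruned_const exactly
        dead = (lam <= lam_floor * (1.0 + 1e-6)) & (
            w_mass * H.sum(axis=1) < 1e-8
        )
        if dead.any() and (~dead).any():
            pruned_const += float(
                np.sum((w_mass[dead] + h_sq[dead] + b) / lam[dead])
                + coef * np.sum(np.log(lam[dead]))
            )
            keep = ~dead
            W, H, lam = W[:, keep], H[keep], lam[keep]
            Vhat = np.maximum(W @ H, _EPS)
            continue  # skip the convergence check on a pruning iteration
        if rel < tol:
            converged = True
            break
    trace = trace[: it + 1]

    # final sweep with the same criterion (e.g. a component that died on the
    # last iteration)
    w_mass = W.sum(axis=0)
    dead = (lam <= lam_floor * (1.0 + 1e-6)) & (w_mass * H.sum(axis=1) < 1e-8)
    keep = ~dead
    if not keep.any():
        keep = np.array([np.argmax(lam) == k for k in range(len(lam))])
    return FactorizationResult(
        W=W[:, keep],
        H=H[keep],
        lam=lam[keep],
        K_final=int(keep.sum()),
        objective_trace=trace,
        converged=converged,
        n_iter=it + 1,
    )


def _as_dense(V) -> np.ndarray:
    return np.asarray(V.todense(), dtype=float) if sp.issparse(V) else np.asarray(V, dtype=float)


def fit_ardnmf(V, config: ArdNmfConfig, rng=None) -> FactorizationResult:
    """One ARD-NMF fit of a genes x cells matrix (no holdout, no restarts)."""
    V = _as_dense(V)
    if V.min() < 0:
        raise ValueError("V must be nonnegative")
    rng = np.random.default_rng(config.seed if rng is None else rng)
    b = config.b if config.b is not None else compute_b(config.a, V, config.K_init)
    return _fit_single(V, config.K_init, config.a, b, config.max_iter, config.tol, rng)


def project_holdout(
    W: np.ndarray, V_heldout, max_iter: int = 2000, tol: float = 1e-6
) -> tuple[np.ndarray, float]:
    """Estimate H for held-out cells with W fixed; returns (H, KL divergence).

    Pure-likelihood (penalty-free) multiplicative KL updates on H; the
    divergence reported is D_KL(V_heldout | W H).
    """
    V = _as_dense(V_heldout)
    if V.shape[0] != W.shape[0]:
        raise ValueError("gene dimension of V_heldout must match W")
    K, C = W.shape[1], V.shape[1]
    rngless_scale = np.sqrt(max(V.mean(), _EPS) / K) / max(W.mean(), _EPS)
    H = np.full((K, C), rngless_scale + _EPS)
    colsum = np.maximum(W.sum(axis=0)[:, None], _EPS)
    prev = np.inf
    div = np.inf
    for _ in range(max_iter):
        Vhat = np.maximum(W @ H, _EPS)
        H *= (W.T @ (V / Vhat)) / colsum
        H = np.maximum(H, _EPS)
        div = _kl_div(V, W @ H)
        if np.isfinite(prev) and abs(prev - div) <= tol * max(abs(prev), 1.0):
            break
        prev = div
    return H, float(div)


def select_solution(results: list[FactorizationResult]) -> FactorizationResult:
    """Restrict to the modal final rank (ties -> smaller K) and return the
    solution with the lowest held-out divergence."""
    if not results:
        raise ValueError("no restart results")
    ks = np.array([r.K_final for r in results])
    vals, counts = np.unique(ks, return_counts=True)
    modal_k = int(vals[counts == counts.max()].min())
    candidates = [r for r in results if r.K_final == modal_k]
    divs = [r.heldout_divergence for r in candidates]
    if np.all(np.isnan(divs)):
        order = [np.min(r.objective_trace) for r in candidates]
        return candidates[int(np.argmin(order))]
    return candidates[int(np.nanargmin(divs))]


def fit_restarts(V, config: ArdNmfConfig) -> tuple[FactorizationResult, list[FactorizationResult]]:
    """Run restarts with a shared cell holdout; select by modal rank + holdout divergence.

    Returns (selected, all restart results).  The holdout split and per-
    restart seeds all derive from ``config.seed``.
    """
    V = _as_dense(V)
    ss = np.random.SeedSequence(config.seed)
    split_rng = np.random.default_rng(ss.spawn(1)[0])
    C = V.shape[1]
    n_hold = int(round(config.holdout_fraction * C))
    perm = split_rng.permutation(C)
    hold_idx, train_idx = perm[:n_hold], perm[n_hold:]
    V_train = V[:, train_idx] if n_hold else V
    V_hold = V[:, hold_idx] if n_hold else None
    b = config.b if config.b is not None else compute_b(config.a, V_train, config.K_init)

    results = []
    for child in ss.spawn(config.n_restarts + 1)[1:]:
        rng = np.random.default_rng(child)
        res = _fit_single(
            V_train, config.K_init, config.a, b, config.max_iter, config.tol, rng
        )
        if V_hold is not None and V_hold.shape[1]:
            _, res.heldout_divergence = project_holdout(res.W, V_hold)
        results.append(res)
    return select_solution(results), results


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------


def normalize_factors(result: FactorizationResult) -> FactorizationResult:
    """Normalize W columns to sum 1, shifting the weight into H (WH unchanged)."""
    sums = result.W.sum(axis=0)
    keep = sums > 0
    if not keep.all():
        warnings.warn(f"pruning {int((~keep).sum())} zero-weight signatures")
    W = result.W[:, keep] / sums[keep]
    H = result.H[keep] * sums[keep][:, None]
    return FactorizationResult(
        W=W,
        H=H,
        lam=result.lam[keep],
        K_final=int(keep.sum()),
        objective_trace=result.objective_trace,
        heldout_divergence=result.heldout_divergence,
        converged=result.converged,
        seed=result.seed,
        n_iter=result.n_iter,
    )


def normalize_activities_per_cell(H: np.ndarray, cell_totals) -> np.ndarray:
    """Divide each cell's activity column by that cell's total counts.

    Cells with zero totals are excluded (columns of NaN) with a warning.
    """
    totals = np.asarray(cell_totals, dtype=float)
    if totals.shape[0] != H.shape[1]:
        raise ValueError("cell_totals must align with H columns")
    bad = totals <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} cells with zero totals excluded from activities")
    out = np.full_like(H, np.nan, dtype=float)
    out[:, ~bad] = H[:, ~bad] / totals[~bad][None, :]
    return out


def classify_signatures(
    H_norm: np.ndarray,
    W: np.ndarray,
    patient_of_cell,
    sd_factor: float = 4.0,
    top_gap: float = 0.5,
) -> pd.Series:
    """Per-signature class: patient_specific, single_gene, or interpretable.

    patient_specific: some patient's mean activity exceeds the mean of the
    other patients' means by ``sd_factor`` of their SD.  single_gene: in the
    sum-1-normalized W column, the top weight beats the runner-up by at
    least ``top_gap``.
    """
    patients = np.asarray(patient_of_cell)
    uniq = pd.unique(patients)
    K = H_norm.shape[0]
    classes = []
    Wn = W / np.maximum(W.sum(axis=0, keepdims=True), _EPS)
    if len(uniq) < 2:
        warnings.warn("patient-specific rule needs >= 2 patients; skipped")
    for k in range(K):
        is_ps = False
        if len(uniq) >= 2:
            means = np.array(
                [np.nanmean(H_norm[k, patients == pt]) for pt in uniq]
            )
            for i in range(len(uniq)):
                others = np.delete(means, i)
                sd = np.std(others, ddof=1) if len(others) > 1 else 0.0
                if means[i] > others.mean() + sd_factor * sd:
                    is_ps = True
                    break
        if is_ps:
            classes.append("patient_specific")
            continue
        col = np.sort(Wn[:, k])[::-1]
        if len(col) >= 2 and col[0] - col[1] >= top_gap:
            classes.append("single_gene")
        else:
            classes.append("interpretable")
    return pd.Series(classes, index=[f"W{k + 1}" for k in range(K)], name="class")


def specificity_scores(W: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Per-gene signature specificity s_{g,k}.

    s_{g,k} = [H 1]_k w_{g,k} / sum_k' [H 1]_k' w_{g,k'} — the fraction of a
    gene's activity-weighted factor weight attributable to signature k.
    Genes with all-zero weights get 0 across signatures.
    """
    h_tot = H.sum(axis=1)  # [H . 1]_k
    raw = W * h_tot[None, :]
    denom = raw.sum(axis=1, keepdims=True)
    s = np.zeros_like(raw)
    nz = denom.ravel() > 0
    s[nz] = raw[nz] / denom[nz]
    return s


def rank_genes(
    W: np.ndarray, specificity: np.ndarray, gene_names, n_top: int = 10
) -> dict[str, list[str]]:
    """Top genes per signature, ranked by weight times specificity."""
    names = np.asarray(gene_names)
    importance = W * specificity
    out = {}
    for k in range(W.shape[1]):
        order = np.argsort(importance[:, k])[::-1][:n_top]
        out[f"W{k + 1}"] = [str(n) for n in names[order]]
    return out


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------


class ARDNMF(TransformerMixin, BaseEstimator):
    """ARD-NMF decomposition of cells x genes count data.

    Follows the sklearn decomposition convention: ``fit(X)`` with X of shape
    (n_cells, n_genes); ``transform`` returns per-cell signature activities
    (n_cells, n_components_); ``components_`` holds the sum-1-normalized
    signatures (n_components_, n_genes).  Internally the genes x cells
    orientation is used.

    Parameters mirror :class:`ArdNmfConfig`; ``n_components`` is the initial
    rank, the effective rank is discovered and exposed as ``n_components_``.
    """

    def __init__(
        self,
        n_components: int = 50,
        a: float = 10.0,
        b: float | None = None,
        max_iter: int = 7000,
        tol: float = 1e-5,
        n_restarts: int = 100,
        holdout_fraction: float = 0.2,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.a = a
        self.b = b
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.holdout_fraction = holdout_fraction
        self.random_state = random_state

    def _config(self) -> ArdNmfConfig:
        return ArdNmfConfig(
            K_init=self.n_components,
            max_iter=self.max_iter,
            tol=self.tol,
            a=self.a,
            b=self.b,
            n_restarts=self.n_restarts,
            holdout_fraction=self.holdout_fraction,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        V = _as_dense(X).T  # genes x cells
        if V.min() < 0:
            raise ValueError("counts must be nonnegative")
        selected, restarts = fit_restarts(V, self._config())
        selected = normalize_factors(selected)
        self.result_ = selected
        self.components_ = selected.W.T
        self.relevance_ = selected.lam
        self.n_components_ = selected.K_final
        self.objective_trace_ = selected.objective_trace
        self.heldout_divergence_ = selected.heldout_divergence
        self.converged_ = selected.converged
        self.restart_summary_ = pd.DataFrame(
            {
                "K_final": [r.K_final for r in restarts],
                "heldout_divergence": [r.heldout_divergence for r in restarts],
                "n_iter": [r.n_iter for r in restarts],
                "converged": [r.converged for r in restarts],
            }
        )
        return self.transform(X)

    def transform(self, X):
        """Per-cell activities with the fitted signatures held fixed."""
        if not hasattr(self, "result_"):
            raise RuntimeError("fit the estimator first")
        V = _as_dense(X).T
        H, _ = project_holdout(self.result_.W, V)
        return H.T
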