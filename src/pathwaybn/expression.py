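"""Expression-matrix handling: loading, missing-value filtering, imputation,
and Gaussian-mixture EM clustering with cross-validated model selection.

The matrix is genes × conditions.  Clustering groups genes by the similarity
of their expression profiles; the clusters later guide which candidate genes
are sampled into a pathway reconstruction.  The mixture uses diagonal
covariances, a variance floor to survive degenerate rows, and an explicit
seed so every fit is reproducible.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-6
EM_MAX_ITERS = 500
EM_REL_TOL = 1e-6


@dataclass
class ExpressionMatrix:
    """Genes × conditions real matrix with an explicit missingness mask."""

    gene_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if self.values.shape != (len(self.gene_ids), len(self.condition_ids)):
            raise ValueError("value matrix shape does not match ids")
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("mask shape does not match values")

    @property
    def M(self) -> int:
        """Number of conditions — the data size of the network score."""
        return len(self.condition_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene)]

    def subset(self, genes: list[str]) -> "ExpressionMatrix":
        idx = [self.gene_ids.index(g) for g in genes]
        return ExpressionMatrix(list(genes), list(self.condition_ids),
                                self.values[idx].copy(), self.missing_mask[idx].copy())

    @classmethod
    def from_tsv(cls, text: str) -> "ExpressionMatrix":
        """Read a TSV with condition-id header, gene ids in the first column;
        empty cells or "NA" mark missing values."""
        df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0,
                         na_values=["NA", ""], keep_default_na=True)
        values = df.to_numpy(dtype=float)
        mask = np.isnan(values)
        values = np.where(mask, 0.0, values)
        return cls([str(g) for g in df.index], [str(c) for c in df.columns], values, mask)

    def to_tsv(self) -> str:
        vals = self.values.astype(object)
        vals[self.missing_mask] = np.nan
        df = pd.DataFrame(vals, index=self.gene_ids, columns=self.condition_ids)
        df.index.name = "gene_id"
        return df.to_csv(sep="\t", na_rep="NA")


@dataclass
class ClusterModel:
    """Diagonal-covariance Gaussian mixture over gene expression profiles."""

    n_clusters: int
    means: np.ndarray              # (k, M)
    variances: np.ndarray          # (k, M), all > 0
    mixing_weights: np.ndarray     # (k,), sums to 1
    assignments: dict[str, int]    # gene -> argmax-responsibility cluster
    loglik_trace: list[float] = field(default_factory=list)
    heldout_loglik: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(float(self.mixing_weights.sum()) - 1.0) > 1e-9:
            raise ValueError("mixing weights must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")

    def cluster_members(self, cluster: int) -> list[str]:
        return sorted(g for g, c in self.assignments.items() if c == cluster)

    def to_json(self) -> str:
        return json.dumps({
            "n_clusters": self.n_clusters,
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "mixing_weights": self.mixing_weights.tolist(),
            "assignments": self.assignments,
            "heldout_loglik": {str(k): v for k, v in self.heldout_loglik.items()},
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ClusterModel":
        d = json.loads(text)
        return cls(d["n_clusters"], np.array(d["means"]), np.array(d["variances"]),
                   np.array(d["mixing_weights"]), {g: int(c) for g, c in d["assignments"].items()},
                   heldout_loglik={int(k): v for k, v in d.get("heldout_loglik", {}).items()})


def filter_missing(matrix: ExpressionMatrix,
                   max_missing_fraction: float = 0.2) -> ExpressionMatrix:
    """Drop genes whose missing fraction *strictly* exceeds the threshold.

    A gene with exactly the threshold fraction of gaps is kept; the rule is
    "more than", not "at least".  Gene order is preserved.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must lie in [0, 1]")
    frac = matrix.missing_mask.mean(axis=1)
    keep = frac <= max_missing_fraction + 1e-12
    if not keep.any():
        raise ValueError("missing-value filter removed every gene")
    genes = [g for g, k in zip(matrix.gene_ids, keep) if k]
    return ExpressionMatrix(genes, list(matrix.condition_ids),
                            matrix.values[keep].copy(), matrix.missing_mask[keep].copy())


def impute(matrix: ExpressionMatrix, method: str = "row_mean",
           k: int = 10) -> ExpressionMatrix:
    """Fill every gap; observed entries are passed through bit-identically.

    ``row_mean`` replaces a gap by the gene's observed mean.  ``knn`` replaces
    it by the mean, at that condition, of the k nearest genes (root mean
    squared difference over jointly observed conditions) that are observed
    there; it falls back to the row mean if no neighbour qualifies.
    """
    if method not in ("row_mean", "knn"):
        raise ValueError(f"unknown imputation method {method!r}")
    obs = ~matrix.missing_mask
    if not obs.any(axis=1).all():
        bad = [g for g, o in zip(matrix.gene_ids, obs.any(axis=1)) if not o]
        raise ValueError(f"genes with no observed values (filter first): {bad}")
    values = matrix.values.copy()
    n, m = values.shape
    row_means = np.where(obs, values, 0.0).sum(axis=1) / obs.sum(axis=1)
    if method == "row_mean":
        values[matrix.missing_mask] = np.repeat(row_means, m).reshape(n, m)[matrix.missing_mask]
    else:
        for i in range(n):
            gaps = np.flatnonzero(matrix.missing_mask[i])
            for j in gaps:
                dists = []
                for other in range(n):
                    if other == i or not obs[other, j]:
                        continue
                    shared = obs[i] & obs[other]
                    if not shared.any():
                        continue
                    diff = values[i, shared] - values[other, shared]
                    dists.append((float(np.sqrt(np.mean(diff ** 2))), other))
                dists.sort()
                if dists:
                    neighbours = [o for _, o in dists[:k]]
                    values[i, j] = float(np.mean(values[neighbours, j]))
                else:
                    values[i, j] = row_means[i]
    return ExpressionMatrix(list(matrix.gene_ids), list(matrix.condition_ids),
                            values, np.zeros_like(matrix.missing_mask))


def _mixture_log_densities(X: np.ndarray, means: np.ndarray, variances: np.ndarray,
                           weights: np.ndarray) -> np.ndarray:
    """Per-sample, per-component log(weight * N(x | mean, diag(var)))."""
    # (n, k) via broadcasting over the condition axis
    diff = X[:, None, :] - means[None, :, :]
    log_norm = -0.5 * (np.log(2 * np.pi * variances)).sum(axis=1)      # (k,)
    quad = -0.5 * (diff ** 2 / variances[None, :, :]).sum(axis=2)      # (n, k)
    return np.log(weights)[None, :] + log_norm[None, :] + quad


def mixture_loglik(X: np.ndarray, means: np.ndarray, variances: np.ndarray,
                   weights: np.ndarray) -> float:
    """Total log-likelihood of rows of X under the mixture."""
    return float(logsumexp(_mixture_log_densities(X, means, variances, weights), axis=1).sum())


def _kmeanspp_means(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Spread-out initial means: each next centre drawn ∝ squared distance."""
    n = X.shape[0]
    centres = [X[rng.integers(n)]]
    for _ in range(k - 1):
        d2 = np.min([np.sum((X - c) ** 2, axis=1) for c in centres], axis=0)
        if d2.sum() <= 0:
            centres.append(X[rng.integers(n)])
            continue
        centres.append(X[rng.choice(n, p=d2 / d2.sum())])
    return np.array(centres, dtype=float)


def _em_once(X: np.ndarray, k: int, rng: np.random.Generator,
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float]]:
    means = _kmeanspp_means(X, k, rng)
    base_var = np.maximum(X.var(axis=0), VARIANCE_FLOOR)
    variances = np.tile(base_var, (k, 1))
    weights = np.full(k, 1.0 / k)
    trace: list[float] = []
    prev = -np.inf
    for _ in range(EM_MAX_ITERS):
        log_dens = _mixture_log_densities(X, means, variances, weights)
        norm = logsumexp(log_dens, axis=1)
        loglik = float(norm.sum())
        trace.append(loglik)
        if np.isfinite(prev) and abs(loglik - prev) <= EM_REL_TOL * max(1.0, abs(prev)):
            break
        prev = loglik
        resp = np.exp(log_dens - norm[:, None])            # (n, k)
        nk = resp.sum(axis=0) + 1e-12
        weights = nk / nk.sum()
        means = (resp.T @ X) / nk[:, None]
        sq = (X[:, None, :] - means[None, :, :]) ** 2
        variances = np.maximum((resp[:, :, None] * sq).sum(axis=0) / nk[:, None],
                               VARIANCE_FLOOR)
    return means, variances, weights, trace


def em_fit(matrix: ExpressionMatrix, k: int, seed: int, n_init: int = 4) -> ClusterModel:
    """Fit a k-component diagonal Gaussian mixture to gene rows by EM.

    Runs ``n_init`` seeded EM restarts from k-means++-style initial means and
    keeps the fit with the best final training log-likelihood; each run stops
    when the relative log-likelihood change drops below 1e-6 or after 500
    iterations.  Component variances are floored at 1e-6.  Deterministic for
    a given seed.
    """
    if k < 1:
        raise ValueError("k must be ≥ 1")
    X = matrix.values
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of genes ({n})")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_init)):
        fit = _em_once(X, k, rng)
        if best is None or fit[3][-1] > best[3][-1]:
            best = fit
    means, variances, weights, trace = best
    log_dens = _mixture_log_densities(X, means, variances, weights)
    hard = log_dens.argmax(axis=1)
    assignments = {g: int(c) for g, c in zip(matrix.gene_ids, hard)}
    return ClusterModel(k, means, variances, weights, assignments, loglik_trace=trace)


def select_num_clusters(matrix: ExpressionMatrix, k_min: int, k_max: int,
                        folds: int = 10, seed: int = 0) -> int:
    """Choose k by cross-validated held-out log-likelihood over gene folds.

    For each candidate k the mixture is fit on the training genes of each fold
    and scored on the held-out genes; the k with the highest mean per-gene
    held-out log-likelihood wins, ties going to the smaller k.
    """
    n = matrix.n_genes
    if not (1 <= k_min <= k_max <= n):
        raise ValueError("need 1 ≤ k_min ≤ k_max ≤ number of genes")
    if folds < 2:
        raise ValueError("folds must be ≥ 2")
    if k_min == k_max:
        return k_min
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_ids = [f for f in np.array_split(perm, min(folds, n)) if len(f)]
    scores: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        fold_scores = []
        for f, held in enumerate(fold_ids):
            train = np.setdiff1d(perm, held)
            if len(train) < k:
                continue
            sub = ExpressionMatrix([matrix.gene_ids[i] for i in train],
                                   list(matrix.condition_ids),
                                   matrix.values[train], matrix.missing_mask[train])
            model = em_fit(sub, k, seed=seed * 1009 + 31 * k + f)
            ll = mixture_loglik(matrix.values[held], model.means,
                                model.variances, model.mixing_weights)
            fold_scores.append(ll / len(held))
        scores[k] = float(np.mean(fold_scores)) if fold_scores else -np.inf
    best = max(scores, key=lambda k: (scores[k], -k))
    return best


def cluster_distance(model: ClusterModel, a: int, b: int) -> float:
    """Euclidean distance between the mean profiles of two clusters."""
    k = model.n_clusters
    if not (0 <= a < k and 0 <= b < k):
        raise IndexError(f"cluster index out of range (k={k}): {a}, {b}")
    return float(np.linalg.norm(model.means[a] - model.means[b]))


def assignments_to_tsv(model: ClusterModel) -> str:
    lines = ["gene_id\tcluster"]
    lines += [f"{g}\t{c}" for g, c in sorted(model.assignments.items())]
    return "\n".join(lines) + "\n"
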