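"""Resampling-based consensus clustering with CDF/ΔAUC model selection.

Per iteration a fraction of samples is drawn without replacement and
clustered at each K with the base clusterer; the consensus matrix is the
fraction of co-sampled iterations in which a pair co-clustered. Final
assignments come from average-linkage hierarchical clustering of
(1 - consensus). The CDF of lower-triangle consensus values gives an
AUC per K, and the relative AUC change (ΔAUC) guides the choice of K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist, squareform
from scipy.stats import median_abs_deviation

from .io_core import ExpressionMatrix

__all__ = [
    "ConsensusResult",
    "PcaResult",
    "select_variable_genes",
    "run_consensus",
    "consensus_cdf_and_auc",
    "pca_embed",
    "suggest_k",
    "cluster_percentages",
]

CDF_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)


@dataclass
class ConsensusResult:
    """Per-K consensus matrices, assignments, and CDF/AUC diagnostics."""

    sample_ids: list[str]
    k_range: list[int]
    consensus: dict[int, np.ndarray]
    cosample_counts: dict[int, np.ndarray]
    assignments: dict[int, np.ndarray]  # labels 1..K per sample
    cdf: dict[int, np.ndarray] = field(default_factory=dict)
    auc: dict[int, float] = field(default_factory=dict)
    delta_auc: dict[int, float] = field(default_factory=dict)
    params: dict = field(default_factory=dict)


def select_variable_genes(matrix: ExpressionMatrix, n: int,
                          criterion: str = "mad") -> list[str]:
    """Top-n genes by descending MAD across samples (ties: gene id order)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if n > matrix.n_genes:
        raise ValueError(f"n={n} exceeds {matrix.n_genes} genes")
    if criterion != "mad":
        raise ValueError(f"unknown criterion {criterion!r}")
    mad = median_abs_deviation(matrix.values, axis=1, scale=1.0)
    order = sorted(range(matrix.n_genes),
                   key=lambda i: (-mad[i], matrix.gene_ids[i]))
    return [matrix.gene_ids[i] for i in order[:n]]


def _base_cluster(data: np.ndarray, k: int, method: str) -> np.ndarray:
    """Cluster columns (samples) of a genes x samples block into k groups."""
    if method == "hier_pearson":
        x = data.T
        # correlation distance degenerates for constant rows; jitter-free guard
        sd = x.std(axis=1)
        if np.any(sd == 0):
            x = x + 1e-9 * np.arange(x.shape[1])[None, :]
        d = pdist(x, metric="correlation")
        d = np.clip(np.nan_to_num(d, nan=1.0), 0.0, None)
        return fcluster(average(d), t=k, criterion="maxclust")
    if method == "kmeans":
        from sklearn.cluster import KMeans
        km = KMeans(n_clusters=k, n_init=5, random_state=0)
        return km.fit_predict(data.T) + 1
    raise ValueError(f"unknown base clusterer {method!r}")


def run_consensus(matrix: ExpressionMatrix, genes: list[str],
                  k_range=range(2, 11), n_iterations: int = 2000,
                  subsample_fraction: float = 0.8,
                  base_clusterer: str = "hier_pearson",
                  seed: int = 0) -> ConsensusResult:
    """Resampled consensus clustering of samples over a gene subset.

    The master seed spawns one RNG stream per iteration, so results are
    independent of iteration execution order.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")
    sub = matrix.subset_genes(genes)
    n = sub.n_samples
    m = int(np.ceil(subsample_fraction * n))
    k_range = sorted(int(k) for k in k_range)
    if k_range[0] < 2:
        raise ValueError("K must be >= 2")
    if k_range[-1] > m:
        raise ValueError(f"K={k_range[-1]} exceeds subsample size {m}")

    co_cluster = {k: np.zeros((n, n)) for k in k_range}
    co_sample = np.zeros((n, n))
    streams = np.random.SeedSequence(seed).spawn(n_iterations)
    for it in range(n_iterations):
        rng = np.random.default_rng(streams[it])
        idx = np.sort(rng.choice(n, size=m, replace=False))
        co_sample[np.ix_(idx, idx)] += 1
        block = sub.values[:, idx]
        for k in k_range:
            labels = _base_cluster(block, k, base_clusterer)
            same = labels[:, None] == labels[None, :]
            co_cluster[k][np.ix_(idx, idx)] += same

    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = {k: np.where(co_sample > 0, co_cluster[k] / co_sample,
                                 np.nan) for k in k_range}
    assignments = {}
    for k in k_range:
        cmat = np.nan_to_num(consensus[k], nan=0.0)
        np.fill_diagonal(cmat, 1.0)
        d = squareform(1.0 - cmat, checks=False)
        assignments[k] = fcluster(average(d), t=k, criterion="maxclust")

    result = ConsensusResult(
        sample_ids=list(sub.sample_ids),
        k_range=k_range,
        consensus=consensus,
        cosample_counts={k: co_sample.copy() for k in k_range},
        assignments=assignments,
        params={"n_genes_selected": len(genes),
                "n_iterations": n_iterations,
                "subsample_fraction": subsample_fraction,
                "base_clusterer": base_clusterer, "seed": seed},
    )
    return consensus_cdf_and_auc(result)


def consensus_cdf_and_auc(result: ConsensusResult) -> ConsensusResult:
    """Fill CDF (101-point grid), trapezoid AUC and relative ΔAUC per K.

    The CDF runs over defined (co-sampled) lower-triangle pairs only.
    ΔAUC at the first K is its AUC; afterwards (AUC_k - AUC_prev)/AUC_prev.
    """
    prev_auc = None
    for k in result.k_range:
        cmat = result.consensus[k]
        tri = cmat[np.tril_indices_from(cmat, k=-1)]
        vals = tri[~np.isnan(tri)]
        if vals.size == 0:
            raise ValueError("no defined sample pairs; cannot build CDF")
        cdf = np.searchsorted(np.sort(vals), CDF_GRID, side="right") / vals.size
        auc = float(np.trapezoid(cdf, CDF_GRID))
        result.cdf[k] = cdf
        result.auc[k] = auc
        if prev_auc is None:
            result.delta_auc[k] = auc
        else:
            result.delta_auc[k] = (auc - prev_auc) / prev_auc
        prev_auc = auc
    return result


def suggest_k(result: ConsensusResult, min_delta: float = 0.025) -> int:
    """Largest K whose relative AUC gain is still non-negligible.

    Encodes the "diminishing gains" reading of the ΔAUC curve: pick the
    last K with ΔAUC >= ``min_delta`` before the curve flattens. This is
    a reported suggestion; the analysis keeps K as an explicit,
    confirmable parameter.
    """
    candidates = [k for k in result.k_range
                  if result.delta_auc[k] >= min_delta]
    return max(candidates) if candidates else result.k_range[0]


def cluster_percentages(labels, decimals: int = 1) -> dict[str, float]:
    """Cluster sizes as percentages of the cohort, rounded for reporting."""
    labels = np.asarray(labels)
    n = labels.size
    if n == 0:
        raise ValueError("no labels")
    out = {}
    for u in np.unique(labels):
        out[str(u)] = float(round(100.0 * (labels == u).sum() / n, decimals))
    return out


@dataclass
class PcaResult:
    """Sample scores, unit-norm gene loadings and variance fractions."""

    sample_ids: list[str]
    gene_ids: list[str]
    scores: np.ndarray      # samples x components
    loadings: np.ndarray    # genes x components
    variance_explained: np.ndarray

    def loading_series(self, component: int) -> dict[str, float]:
        return dict(zip(self.gene_ids, self.loadings[:, component]))


def pca_embed(matrix: ExpressionMatrix, genes: list[str] | None = None,
              n_components: int | None = None) -> PcaResult:
    """Gene-centered SVD of samples over a gene subset.

    Component signs are fixed so the largest-magnitude loading in each
    component is positive.
    """
    if matrix.n_samples < 2:
        raise ValueError("PCA needs >= 2 samples")
    sub = matrix.subset_genes(list(genes)) if genes is not None else matrix
    x = sub.values.T  # samples x genes
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    total_var = (xc ** 2).sum()
    if total_var == 0:
        var_exp = np.zeros(s.size)
    else:
        var_exp = s ** 2 / total_var
    if n_components is not None:
        u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
        var_exp = var_exp[:n_components]
    loadings = vt.T  # genes x comps, unit columns
    signs = np.sign(loadings[np.abs(loadings).argmax(axis=0),
                             np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    loadings = loadings * signs
    scores = u * s * signs
    return PcaResult(list(sub.sample_ids), list(sub.gene_ids),
                     scores, loadings, var_exp)
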