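"""Per-cell signed module scores, KNN smoothing, gene-set enrichment.

Covers: positive-minus-negative per-cell module scores with KNN
smoothing over an expression embedding; per-type score summaries;
single-sample gene-set scores (weighted-ECDF rank statistic); preranked
running-sum enrichment with a gene-label permutation null; and Spearman
association with exact small-sample permutation p-values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ExpressionMatrix, GeneSetCollection
from .markers import CellTable

__all__ = [
    "ScoreVector",
    "EnrichmentRow",
    "degeneration_score",
    "knn_smooth",
    "summarize_scores",
    "ssgsea_sample_scores",
    "preranked_gsea",
    "spearman_assoc",
]


@dataclass
class ScoreVector:
    """Raw and (optionally) smoothed per-cell signed module scores."""

    cell_ids: list[str]
    raw: np.ndarray
    smoothed: np.ndarray | None = None
    pos_set: str = "pos"
    neg_set: str = "neg"
    k: int | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.size != len(self.cell_ids):
            raise ValueError("raw scores must align with cell ids")
        if self.smoothed is not None:
            self.smoothed = np.asarray(self.smoothed, dtype=float)
            if self.smoothed.size != len(self.cell_ids):
                raise ValueError("smoothed scores must align with cell ids")

    @property
    def values(self) -> np.ndarray:
        return self.smoothed if self.smoothed is not None else self.raw


def degeneration_score(cells: CellTable, pos_genes, neg_genes,
                       pos_name: str = "pos", neg_name: str = "neg"
                       ) -> ScoreVector:
    """Mean normalized expression of the positive set minus the negative set."""
    pos = [g for g in dict.fromkeys(pos_genes) if g in cells.gene_ids]
    neg = [g for g in dict.fromkeys(neg_genes) if g in cells.gene_ids]
    if not pos or not neg:
        side = "positive" if not pos else "negative"
        raise ValueError(f"{side} gene set has no genes in the cell universe")
    lookup = {g: i for i, g in enumerate(cells.gene_ids)}
    pos_idx = [lookup[g] for g in pos]
    neg_idx = [lookup[g] for g in neg]
    raw = cells.normalized[:, pos_idx].mean(axis=1) \
        - cells.normalized[:, neg_idx].mean(axis=1)
    return ScoreVector(list(cells.cell_ids), raw, pos_set=pos_name,
                       neg_set=neg_name)


def knn_smooth(scores: ScoreVector, embedding: np.ndarray, k: int = 15,
               chunk: int = 2048) -> ScoreVector:
    """Replace each score by the mean over the cell and its k nearest
    Euclidean neighbors in the embedding.

    k = 0 is the identity. Distance ties are broken by cell index
    (stable sort), so the result is deterministic.
    """
    embedding = np.asarray(embedding, dtype=float)
    n = scores.raw.size
    if embedding.shape[0] != n:
        raise ValueError("embedding rows must align with cells")
    if k < 0 or k >= n:
        raise ValueError("need 0 <= k < number of cells")
    if k == 0:
        return ScoreVector(scores.cell_ids, scores.raw, scores.raw.copy(),
                           scores.pos_set, scores.neg_set, k=0)
    smoothed = np.empty(n)
    sq = (embedding ** 2).sum(axis=1)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        block = embedding[start:stop]
        d2 = sq[None, :] - 2 * block @ embedding.T + (block ** 2).sum(axis=1)[:, None]
        np.maximum(d2, 0.0, out=d2)
        rows = np.arange(start, stop)
        d2[np.arange(stop - start), rows] = -1.0  # self first
        order = np.argsort(d2, axis=1, kind="stable")[:, :k + 1]
        smoothed[start:stop] = scores.raw[order].mean(axis=1)
    return ScoreVector(scores.cell_ids, scores.raw, smoothed,
                       scores.pos_set, scores.neg_set, k=k)


def summarize_scores(scores: ScoreVector, cells: CellTable) -> pd.DataFrame:
    """Per-type median, 25th/75th percentiles (linear interpolation), n."""
    if len(scores.cell_ids) != cells.n_cells:
        raise ValueError("score vector does not align with cell table")
    vals = scores.values
    rows = []
    for t in cells.types:
        mask = cells.cell_type == t
        if not mask.any():
            continue
        v = vals[mask]
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append({"cell_type": t, "median": float(med), "p25": float(q1),
                     "p75": float(q3), "n": int(mask.sum())})
    return pd.DataFrame(rows).sort_values("median", ascending=False,
                                          ignore_index=True)


# ---------------------------------------------------------------------------
# Gene-set scoring
# ---------------------------------------------------------------------------

def _ssgsea_one(expr: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Weighted-ECDF single-sample score for one sample.

    Genes are ranked by expression descending; the in-set ECDF is
    weighted by |rank statistic|^alpha (rank statistic = N..1), the
    out-of-set ECDF is uniform; the score sums their difference.
    """
    n = expr.size
    order = np.argsort(-expr, kind="stable")
    ranks = np.arange(n, 0, -1, dtype=float)  # N for top gene, 1 for bottom
    inset_sorted = in_set[order]
    w = np.where(inset_sorted, np.abs(ranks) ** alpha, 0.0)
    wsum = w.sum()
    if wsum == 0:
        return 0.0
    p_in = np.cumsum(w) / wsum
    n_out = n - in_set.sum()
    if n_out == 0:
        return 0.0
    p_out = np.cumsum(~inset_sorted) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea_sample_scores(matrix: ExpressionMatrix, sets: GeneSetCollection,
                         alpha: float = 0.25, rescale: bool = True
                         ) -> pd.DataFrame:
    """Set x sample single-sample enrichment score matrix.

    Scores are rescaled per set across samples to zero mean and unit
    variance (skipped for constant rows or when ``rescale`` is False).
    Sets with fewer than 2 genes in the universe are skipped.
    """
    universe = set(matrix.gene_ids)
    rows, names, warn = [], [], []
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    for name, genes in sets.items():
        present = [g for g in genes if g in universe]
        if len(present) < 2:
            warn.append(name)
            continue
        in_set = np.zeros(matrix.n_genes, dtype=bool)
        in_set[[gene_pos[g] for g in present]] = True
        scores = np.array([_ssgsea_one(matrix.values[:, j], in_set, alpha)
                           for j in range(matrix.n_samples)])
        rows.append(scores)
        names.append(name)
    if warn:
        import warnings as _warnings
        _warnings.warn(f"sets with < 2 genes in universe skipped: {warn}")
    out = pd.DataFrame(rows, index=names, columns=matrix.sample_ids)
    if rescale and not out.empty:
        sd = out.std(axis=1, ddof=0)
        sd = sd.where(sd > 0, 1.0)
        out = out.sub(out.mean(axis=1), axis=0).div(sd, axis=0)
    return out


@dataclass
class EnrichmentRow:
    """One preranked enrichment result."""

    set_name: str
    es: float
    nes: float
    p_value: float
    direction: str
    n_genes: int
    q_value: float | None = None

    def __post_init__(self) -> None:
        if self.es * self.nes < 0:
            raise ValueError("NES sign must match ES sign")


def _running_es(stat_sorted: np.ndarray, in_set: np.ndarray) -> float:
    """Signed max deviation of the weighted Kolmogorov-Smirnov walk.

    ``stat_sorted`` is the ranking statistic in descending order;
    ``in_set`` flags set members in that order. Weight = |statistic|,
    falling back to the unweighted walk when in-set weights sum to 0.
    """
    n = stat_sorted.size
    m = int(in_set.sum())
    if m == 0 or m == n:
        raise ValueError("set must be a strict non-empty subset")
    w = np.abs(stat_sorted) * in_set
    wsum = w.sum()
    if wsum == 0:
        w = in_set.astype(float)
        wsum = float(m)
    walk = np.where(in_set, w / wsum, -1.0 / (n - m))
    path = np.cumsum(walk)
    i = np.argmax(np.abs(path))
    # cumulative float error can push the walk past +/-1 by an epsilon
    return float(np.clip(path[i], -1.0, 1.0))


def preranked_gsea(ranked_stats: dict[str, float] | pd.Series,
                   gene_set, n_perm: int = 1000, seed: int = 0,
                   set_name: str = "set") -> EnrichmentRow:
    """Preranked enrichment of one gene set against a ranked statistic.

    The null redraws random same-size gene sets (gene-label permutation).
    NES = ES / mean(|null ES| of matching sign); p is the matching-sign
    tail frequency with a +1 pseudocount.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if isinstance(ranked_stats, pd.Series):
        genes = list(ranked_stats.index)
        statvals = ranked_stats.to_numpy(dtype=float)
    else:
        genes = list(ranked_stats)
        statvals = np.array([ranked_stats[g] for g in genes], dtype=float)
    order = np.argsort(-statvals, kind="stable")
    stat_sorted = statvals[order]
    gene_sorted = [genes[i] for i in order]
    members = set(gene_set)
    in_set = np.array([g in members for g in gene_sorted])
    m = int(in_set.sum())
    if m == 0:
        raise ValueError("gene set does not intersect the ranked universe")
    if m == len(gene_sorted):
        raise ValueError("gene set covers the whole universe")
    es = _running_es(stat_sorted, in_set)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    n = len(gene_sorted)
    for b in range(n_perm):
        idx = rng.choice(n, size=m, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        null[b] = _running_es(stat_sorted, mask)
    same = null >= 0 if es >= 0 else null < 0
    same_vals = np.abs(null[same])
    denom = same_vals.mean() if same_vals.size else np.abs(null).mean()
    nes = es / denom if denom > 0 else 0.0
    p = (1 + int((same_vals >= abs(es)).sum())) / (1 + int(same.sum()))
    return EnrichmentRow(set_name=set_name, es=es, nes=float(nes),
                         p_value=float(min(p, 1.0)),
                         direction="up" if es >= 0 else "down", n_genes=m)


def gsea_collection(ranked_stats, sets: GeneSetCollection,
                    n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Run preranked enrichment for every set; BH across sets."""
    from .diffexpr import bh_adjust
    rows = []
    for i, (name, genes) in enumerate(sets.items()):
        try:
            row = preranked_gsea(ranked_stats, genes, n_perm=n_perm,
                                 seed=seed + i, set_name=name)
        except ValueError:
            continue
        rows.append(row)
    df = pd.DataFrame([r.__dict__ for r in rows])
    if not df.empty:
        df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    return df


def spearman_assoc(scores, covariate) -> tuple[float, float]:
    """Tie-corrected Spearman correlation with small-sample exact p.

    Exact permutation enumeration for n <= 9, t-approximation otherwise.
    Constant inputs are rejected (rho undefined).
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 4:
        raise ValueError("need >= 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman rho undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    n = x.size
    if n <= 9:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, float(min(p, 1.0))
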