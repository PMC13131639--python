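"""Cell-type marker derivation and bulk/single-cell cross-referencing.

Markers are selected one-vs-all under conjunctive fold-change and
prevalence thresholds; marker loadings on bulk principal components are
tested with one-sample signed-rank tests; per-cluster mean marker-set
expression is compared to a reference cluster with ANOVA plus Dunnett
many-to-one contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import PcaResult
from .diffexpr import bh_adjust, _ranksum_vectorized
from .io_core import ExpressionMatrix

__all__ = [
    "CellTable",
    "MarkerSet",
    "normalize_counts",
    "sc_markers",
    "loading_enrichment",
    "marker_score_by_cluster",
]


def normalize_counts(counts: np.ndarray, scale: float = 1e4) -> np.ndarray:
    """Per-cell depth normalization to ``scale`` counts, then log1p."""
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    return np.log1p(scale * counts / lib)


@dataclass
class CellTable:
    """Typed single cells: raw counts, log-normalized values, embedding."""

    cell_ids: list[str]
    gene_ids: list[str]
    counts: np.ndarray       # cells x genes
    normalized: np.ndarray   # cells x genes
    cell_type: np.ndarray    # label per cell
    embedding: np.ndarray    # cells x d

    def __post_init__(self) -> None:
        n, g = len(self.cell_ids), len(self.gene_ids)
        self.counts = np.asarray(self.counts)
        self.normalized = np.asarray(self.normalized, dtype=float)
        self.cell_type = np.asarray(self.cell_type, dtype=object)
        self.embedding = np.asarray(self.embedding, dtype=float)
        if self.counts.shape != (n, g):
            raise ValueError("counts shape mismatch")
        if self.normalized.shape != (n, g):
            raise ValueError("normalized shape mismatch")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.cell_type) != n:
            raise ValueError("cell_type length mismatch")
        if self.embedding.shape[0] != n:
            raise ValueError("embedding rows must align with cells")

    @classmethod
    def from_counts(cls, cell_ids, gene_ids, counts, cell_type,
                    embedding_dim: int = 10) -> "CellTable":
        """Build a table from raw counts: normalize and PCA-embed."""
        counts = np.asarray(counts)
        normalized = normalize_counts(counts)
        d = min(embedding_dim, min(counts.shape) - 1) if min(counts.shape) > 1 else 1
        xc = normalized - normalized.mean(axis=0)
        u, s, _ = np.linalg.svd(xc, full_matrices=False)
        embedding = (u * s)[:, :d]
        return cls(list(cell_ids), list(gene_ids), counts, normalized,
                   np.asarray(cell_type, dtype=object), embedding)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def types(self) -> list[str]:
        return sorted(set(self.cell_type))

    def write_tsv(self, prefix: str) -> None:
        pd.DataFrame(self.counts, index=self.cell_ids,
                     columns=self.gene_ids).to_csv(
            f"{prefix}.counts.tsv", sep="\t", index_label="cell_id")
        pd.DataFrame({"cell_id": self.cell_ids,
                      "cell_type": self.cell_type}).to_csv(
            f"{prefix}.types.tsv", sep="\t", index=False)


@dataclass
class MarkerSet:
    """Per-type marker tables, each row a gene passing all thresholds."""

    per_type: dict[str, pd.DataFrame]
    thresholds: dict[str, float] = field(default_factory=dict)

    def genes(self, cell_type: str, top_n: int | None = None) -> list[str]:
        df = self.per_type[cell_type]
        genes = df["gene"].tolist()
        return genes[:top_n] if top_n is not None else genes

    def types(self) -> list[str]:
        return list(self.per_type)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for t, df in self.per_type.items():
            d = df.copy()
            d.insert(0, "cell_type", t)
            frames.append(d)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def sc_markers(cells: CellTable, lfc_min: float = 0.5,
               frac_min: float = 0.40, gap_min: float = 0.10,
               eps: float = 1e-9) -> MarkerSet:
    """One-vs-all marker selection under conjunctive thresholds.

    Per type: rank-sum test on normalized expression, de-logged-mean fold
    change, detection fractions from raw counts. A gene is a marker when
    log2FC >= lfc_min, frac_in >= frac_min and frac_in - frac_out >=
    gap_min. BH correction within type; output sorted by descending
    log2FC (gene id breaking ties).
    """
    types = cells.types
    if len(types) < 2:
        raise ValueError("need >= 2 cell types")
    for t in types:
        if (cells.cell_type == t).sum() < 3:
            raise ValueError(f"cell type {t!r} has < 3 cells")
    detected = cells.counts > 0
    delog = np.expm1(cells.normalized)
    per_type: dict[str, pd.DataFrame] = {}
    for t in types:
        in_mask = cells.cell_type == t
        _, p = _ranksum_vectorized(cells.normalized.T, in_mask)
        mean_in = delog[in_mask].mean(axis=0)
        mean_out = delog[~in_mask].mean(axis=0)
        lfc = np.log2((mean_in + eps) / (mean_out + eps))
        frac_in = detected[in_mask].mean(axis=0)
        frac_out = detected[~in_mask].mean(axis=0)
        q = bh_adjust(p)
        keep = (lfc >= lfc_min) & (frac_in >= frac_min) \
            & (frac_in - frac_out >= gap_min)
        df = pd.DataFrame({
            "gene": np.array(cells.gene_ids, dtype=object)[keep],
            "log2_fold_change": lfc[keep],
            "frac_in": frac_in[keep],
            "frac_out": frac_out[keep],
            "p_value": p[keep],
            "q_value": q[keep],
        })
        df = df.sort_values(["log2_fold_change", "gene"],
                            ascending=[False, True], kind="stable",
                            ignore_index=True)
        per_type[t] = df
    return MarkerSet(per_type, {"lfc_min": lfc_min, "frac_min": frac_min,
                                "gap_min": gap_min})


def loading_enrichment(pca: PcaResult, markers: MarkerSet,
                       component: int = 0) -> pd.DataFrame:
    """One-sample signed-rank test of marker loadings against zero.

    Per type: the component's loadings of marker genes present in the
    bulk PCA universe, their median, and a two-sided signed-rank p. Types
    with no markers in the universe appear with NaN statistics.
    """
    loading = pca.loading_series(component)
    rows = []
    for t in markers.types():
        genes = [g for g in markers.genes(t) if g in loading]
        if not genes:
            rows.append({"cell_type": t, "n_genes": 0, "median_loading":
                         np.nan, "p_value": np.nan})
            continue
        vals = np.array([loading[g] for g in genes])
        if np.all(vals == 0):
            p = 1.0
        else:
            mode = "exact" if (len(vals) <= 25 and not np.any(vals == 0)) \
                else "approx"
            p = float(stats.wilcoxon(vals, alternative="two-sided",
                                     method=mode).pvalue)
        rows.append({"cell_type": t, "n_genes": len(vals),
                     "median_loading": float(np.median(vals)),
                     "p_value": p})
    return pd.DataFrame(rows)


def marker_score_by_cluster(bulk: ExpressionMatrix, markers: MarkerSet,
                            labels, reference: str, top_n: int = 20
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean marker-set expression per sample, compared across clusters.

    Per sample the score for a type is the mean logCPM over that type's
    top ``top_n`` markers found in bulk. Per type: one-way ANOVA across
    clusters and Dunnett many-to-one comparisons versus the reference.
    Returns (per-(type, cluster) mean table, per-contrast table).
    """
    labels = np.asarray(labels)
    if labels.size != bulk.n_samples:
        raise ValueError("labels length must match samples")
    uniq = [str(u) for u in np.unique(labels)]
    if str(reference) not in uniq:
        raise ValueError(f"reference {reference!r} not in labels")
    others = [u for u in uniq if u != str(reference)]
    labels = labels.astype(str)

    mean_rows, contrast_rows, skipped = [], [], []
    for t in markers.types():
        genes = [g for g in markers.genes(t, top_n) if g in bulk.gene_ids]
        if not genes:
            skipped.append(t)
            continue
        idx = bulk.gene_index(genes)
        score = bulk.values[idx].mean(axis=0)  # per sample
        groups = {u: score[labels == u] for u in uniq}
        _, anova_p = stats.f_oneway(*groups.values())
        for u in uniq:
            mean_rows.append({"cell_type": t, "cluster": u,
                              "mean_score": float(groups[u].mean()),
                              "n": int(groups[u].size),
                              "anova_p": float(anova_p)})
        res = stats.dunnett(*[groups[u] for u in others],
                            control=groups[str(reference)],
                            random_state=np.random.default_rng(0))
        for u, stat, p in zip(others, np.atleast_1d(res.statistic),
                              np.atleast_1d(res.pvalue)):
            contrast_rows.append({
                "cell_type": t, "cluster": u, "reference": str(reference),
                "statistic": float(stat), "p_adjusted": float(p)})
    if skipped:
        import warnings as _warnings
        _warnings.warn(f"types with no markers in bulk skipped: {skipped}")
    return pd.DataFrame(mean_rows), pd.DataFrame(contrast_rows)
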