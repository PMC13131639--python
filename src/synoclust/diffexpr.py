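"""Differential expression and metadata association testing.

The DE engine is a vectorized two-sided rank-sum test on logCPM with
Benjamini-Hochberg correction; metadata associations dispatch between
Welch ANOVA, Kruskal-Wallis and Fisher's exact tests based on variable
type and a per-group Shapiro-Wilk normality screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .io_core import ExpressionMatrix, SampleMetadata

__all__ = [
    "DEResult",
    "AssociationTable",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "de_cluster_vs_rest",
    "de_degeneration",
    "associate_metadata",
    "welch_anova",
    "fisher_exact_table",
]


# ---------------------------------------------------------------------------
# Primitive tests
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided two-sample rank-sum test.

    ``mode="exact"`` enumerates the null; ``"normal_tie_corrected"`` uses
    the normal approximation with tie and continuity corrections; ``"auto"``
    picks exact when min group size <= 12 and there are no ties. Returns
    (Mann-Whitney U of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("exact", "normal_tie_corrected", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if mode == "auto":
        mode = "exact" if (min(x.size, y.size) <= 12 and not ties) \
            else "normal_tie_corrected"
    if mode == "exact" and ties:
        raise ValueError("exact mode is undefined with ties")
    method = "exact" if mode == "exact" else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def welch_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Welch's one-way ANOVA (unequal variances). Returns (F, p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    n = np.array([g.size for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    if np.any(v == 0):
        v = np.where(v == 0, 1e-12, v)
    w = n / v
    mw = (w * m).sum() / w.sum()
    num = ((w * (m - mw) ** 2).sum()) / (k - 1)
    tmp = ((1 - w / w.sum()) ** 2 / (n - 1)).sum()
    den = 1 + 2 * (k - 2) / (k ** 2 - 1) * tmp
    f = num / den
    df2 = (k ** 2 - 1) / (3 * tmp)
    p = stats.f.sf(f, k - 1, df2)
    return float(f), float(p)


def fisher_exact_table(table: np.ndarray, n_mc: int = 100_000,
                       seed: int = 0) -> float:
    """Two-sided Fisher's exact p for an r x c contingency table.

    2x2 tables are exact (hypergeometric); larger tables use a seeded
    Monte-Carlo permutation of the column variable, scoring tables by
    their conditional multivariate-hypergeometric probability.
    """
    table = np.asarray(table, dtype=int)
    if table.min() < 0:
        raise ValueError("contingency counts must be non-negative")
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 1.0
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table, alternative="two-sided")[1])

    def log_prob(tabs: np.ndarray) -> np.ndarray:
        # tabs: (..., r, c); conditional probability given both margins
        row = tabs.sum(axis=-1)
        col = tabs.sum(axis=-2)
        n = row.sum(axis=-1)
        lp = (gammaln(row + 1).sum(axis=-1) + gammaln(col + 1).sum(axis=-1)
              - gammaln(n + 1) - gammaln(tabs + 1).sum(axis=(-2, -1)))
        return lp

    obs_lp = log_prob(table)
    rows = np.repeat(np.arange(table.shape[0]), table.sum(axis=1))
    cols = np.repeat(np.arange(table.shape[1]), table.sum(axis=0))
    rng = np.random.default_rng(seed)
    n_total = rows.size
    hits = 0
    chunk = max(1, min(n_mc, int(2e7 // max(n_total, 1))))
    done = 0
    r, c = table.shape
    while done < n_mc:
        b = min(chunk, n_mc - done)
        perm = rng.permuted(np.tile(cols, (b, 1)), axis=1)
        tabs = np.zeros((b, r, c), dtype=np.int64)
        for i in range(r):
            sub = perm[:, rows == i]
            tabs[:, i, :] = (sub[:, :, None] == np.arange(c)).sum(axis=1)
        hits += int((log_prob(tabs) <= obs_lp + 1e-9).sum())
        done += b
    return (hits + 1) / (n_mc + 1)


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    """Per-gene DE table: log2FC, statistic, p, BH q, direction."""

    table: pd.DataFrame  # index gene, cols log2_fold_change/statistic/p/q/direction
    contrast: str = ""

    def __post_init__(self) -> None:
        required = {"log2_fold_change", "statistic", "p_value", "q_value",
                    "direction"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"DE table missing columns: {sorted(missing)}")

    def significant(self, q_max: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q_value"] < q_max]

    def up_genes(self, q_max: float = 0.05) -> list[str]:
        sig = self.significant(q_max)
        return sig.index[sig["direction"] == "up"].tolist()

    def down_genes(self, q_max: float = 0.05) -> list[str]:
        sig = self.significant(q_max)
        return sig.index[sig["direction"] == "down"].tolist()


def _ranksum_vectorized(values: np.ndarray, in_group: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-row tie-corrected normal rank-sum p (two-sided, continuity)."""
    n1 = int(in_group.sum())
    n2 = int((~in_group).sum())
    ranks = stats.rankdata(values, axis=1)
    r1 = ranks[:, in_group].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    # tie correction per gene
    sorted_vals = np.sort(values, axis=1)
    tie_term = np.zeros(values.shape[0])
    for i in range(values.shape[0]):
        _, cnt = np.unique(sorted_vals[i], return_counts=True)
        tie_term[i] = (cnt ** 3 - cnt).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(u1 - mu) - 0.5) / sigma
    z = np.where(sigma == 0, 0.0, np.maximum(z, 0.0))
    p = np.minimum(2 * stats.norm.sf(z), 1.0)
    p = np.where(sigma == 0, 1.0, p)
    return u1, p


def _de_binary(matrix: ExpressionMatrix, in_group: np.ndarray, contrast: str,
               expressed_min_frac: float) -> DEResult:
    if matrix.layer != "logcpm":
        raise ValueError("DE expects a logcpm matrix")
    if in_group.sum() < 2 or (~in_group).sum() < 2:
        raise ValueError("both groups need >= 2 samples")
    expressed = (matrix.values > 0).mean(axis=1) >= expressed_min_frac
    genes = [g for g, e in zip(matrix.gene_ids, expressed) if e]
    vals = matrix.values[expressed]
    u, p = _ranksum_vectorized(vals, in_group)
    lfc = vals[:, in_group].mean(axis=1) - vals[:, ~in_group].mean(axis=1)
    constant = vals.std(axis=1) == 0
    lfc = np.where(constant, 0.0, lfc)
    q = bh_adjust(p)
    df = pd.DataFrame({
        "log2_fold_change": lfc,
        "statistic": u,
        "p_value": p,
        "q_value": q,
        "direction": np.where(lfc >= 0, "up", "down"),
    }, index=pd.Index(genes, name="gene"))
    return DEResult(df, contrast)


def de_cluster_vs_rest(matrix: ExpressionMatrix, labels, target,
                       expressed_min_frac: float = 0.10) -> DEResult:
    """Rank-sum DE of one cluster against all remaining samples.

    log2FC is the mean logCPM difference (target minus rest); genes must
    be expressed (nonzero) in >= ``expressed_min_frac`` of samples.
    """
    labels = np.asarray(labels)
    if labels.size != matrix.n_samples:
        raise ValueError("labels length must match samples")
    in_group = labels == target
    if not in_group.any():
        raise ValueError(f"cluster {target!r} not found in labels")
    return _de_binary(matrix, in_group, f"{target}_vs_rest",
                      expressed_min_frac)


def de_degeneration(matrix: ExpressionMatrix, metadata: SampleMetadata,
                    threshold: int = 20,
                    expressed_min_frac: float = 0.10) -> DEResult:
    """DE between high (d_oarsi >= threshold) and lower degeneration samples."""
    meta = metadata.aligned_to(matrix)
    scores = meta.table["d_oarsi"].to_numpy(dtype=float)
    high = scores >= threshold
    if high.all() or not high.any():
        raise ValueError(
            f"threshold {threshold} puts all samples in one stratum")
    return _de_binary(matrix, high, f"d_oarsi_ge_{threshold}",
                      expressed_min_frac)


# ---------------------------------------------------------------------------
# Metadata association
# ---------------------------------------------------------------------------

@dataclass
class AssociationTable:
    """Per-variable test choice, p-value and group summaries."""

    table: pd.DataFrame  # variable, type, test_used, p_value
    summaries: dict[str, pd.DataFrame]
    warnings: list[str]


def _summarize_continuous(groups: dict[str, np.ndarray], normal: bool
                          ) -> pd.DataFrame:
    rows = {}
    for name, vals in groups.items():
        if normal:
            rows[name] = {"mean": float(np.mean(vals)),
                          "sd": float(np.std(vals, ddof=1)), "n": vals.size}
        else:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows[name] = {"median": float(med), "p25": float(q1),
                          "p75": float(q3), "n": vals.size}
    return pd.DataFrame(rows).T


def associate_metadata(metadata: SampleMetadata, labels,
                       shapiro_alpha: float = 0.05,
                       fisher_mc: int = 100_000,
                       seed: int = 0) -> AssociationTable:
    """Test each clinical covariate for association with cluster labels.

    Continuous variables: if the Shapiro-Wilk test is non-significant in
    every cluster, Welch ANOVA with mean/SD summaries; else Kruskal-Wallis
    with median/IQR. Categorical variables: Fisher's exact test on the
    cluster x level table (Monte-Carlo beyond 2x2).
    """
    labels = np.asarray(labels)
    if labels.size != len(metadata.table):
        raise ValueError("labels length must match metadata rows")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need >= 2 clusters")
    counts = np.array([(labels == u).sum() for u in uniq])
    if np.any(counts < 2):
        raise ValueError("every cluster needs >= 2 samples")

    variables = dict(metadata.clinical_types)
    for col in ("d_oarsi", "control_oarsi", "kl_grade"):
        if col in metadata.table.columns and col not in variables:
            variables[col] = "continuous"

    rows, summaries, warnings = [], {}, []
    for var, kind in variables.items():
        series = metadata.table[var]
        valid = series.notna().to_numpy()
        if not valid.any():
            warnings.append(f"variable {var!r} missing for all samples; skipped")
            continue
        lab = labels[valid]
        if kind == "continuous":
            vals = series.to_numpy(dtype=float)[valid]
            groups = {str(u): vals[lab == u] for u in np.unique(lab)}
            if any(g.size < 2 for g in groups.values()):
                warnings.append(f"variable {var!r}: a cluster has < 2 values; skipped")
                continue
            sh_ps = [stats.shapiro(g)[1] if (g.size >= 3 and np.ptp(g) > 0)
                     else 0.0 for g in groups.values()]
            normal = all(p > shapiro_alpha for p in sh_ps)
            if normal:
                _, p = welch_anova(list(groups.values()))
                test = "welch_anova"
            else:
                _, p = stats.kruskal(*groups.values())
                test = "kruskal_wallis"
            summaries[var] = _summarize_continuous(groups, normal)
        else:
            cats = pd.Categorical(series[valid].astype(str))
            tab = pd.crosstab(pd.Series(lab, name="cluster"),
                              pd.Series(cats, name=var))
            p = fisher_exact_table(tab.to_numpy(), n_mc=fisher_mc, seed=seed)
            test = "fisher_exact"
            summ = tab.copy().astype(float)
            summ = (tab.T / tab.sum(axis=1)).T
            summaries[var] = pd.concat(
                {"count": tab, "fraction": summ}, axis=1)
        rows.append({"variable": var, "type": kind, "test_used": test,
                     "p_value": float(p)})
    return AssociationTable(pd.DataFrame(rows), summaries, warnings)
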