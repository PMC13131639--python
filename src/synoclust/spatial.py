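"""Spatial cell-table summaries and region enrichment statistics.

Operations: per-region cell-type composition, fold enrichment of a type
in a region versus a reference scope, per-(gene, type) detection stats,
and region-versus-remainder Fisher tests per gene with BH correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

__all__ = [
    "SpatialCellTable",
    "CompositionSummary",
    "composition",
    "region_fold_enrichment",
    "detection_stats",
    "zoom_gene_enrichment",
    "format_percent",
    "format_fold",
]

WHOLE = "whole"


@dataclass
class SpatialCellTable:
    """Positioned, typed cells with per-gene transcript counts.

    ``region`` labels one named sub-region scheme; the implicit region
    ``"whole"`` always refers to every cell.
    """

    cell_ids: list[str]
    x: np.ndarray
    y: np.ndarray
    cell_type: np.ndarray
    region: np.ndarray
    genes: list[str]
    gene_counts: np.ndarray  # cells x genes, non-negative ints

    def __post_init__(self) -> None:
        n = len(self.cell_ids)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.cell_type = np.asarray(self.cell_type, dtype=object)
        self.region = np.asarray(self.region, dtype=object)
        self.gene_counts = np.asarray(self.gene_counts)
        for name, arr in (("x", self.x), ("y", self.y),
                          ("cell_type", self.cell_type),
                          ("region", self.region)):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} cells")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("coordinates must be finite")
        if self.gene_counts.shape != (n, len(self.genes)):
            raise ValueError("gene_counts shape mismatch")
        if np.any(self.gene_counts < 0):
            raise ValueError("transcript counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def region_mask(self, scope: str) -> np.ndarray:
        if scope == WHOLE:
            return np.ones(self.n_cells, dtype=bool)
        mask = self.region == scope
        if not mask.any():
            raise ValueError(f"region {scope!r} is empty or unknown")
        return mask

    def gene_column(self, gene: str) -> np.ndarray:
        missing = [g for g in [gene] if g not in self.genes]
        if missing:
            raise KeyError(f"gene(s) not in panel: {missing}")
        return self.gene_counts[:, self.genes.index(gene)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "cell_id": self.cell_ids, "x": self.x, "y": self.y,
            "cell_type": self.cell_type, "region": self.region,
        })
        for j, g in enumerate(self.genes):
            df[g] = self.gene_counts[:, j]
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SpatialCellTable":
        df = pd.read_csv(path, sep="\t")
        fixed = ["cell_id", "x", "y", "cell_type", "region"]
        genes = [c for c in df.columns if c not in fixed]
        return cls(cell_ids=df["cell_id"].astype(str).tolist(),
                   x=df["x"].to_numpy(), y=df["y"].to_numpy(),
                   cell_type=df["cell_type"].to_numpy(dtype=object),
                   region=df["region"].to_numpy(dtype=object),
                   genes=genes,
                   gene_counts=df[genes].to_numpy(dtype=int))


@dataclass
class CompositionSummary:
    """Cell counts and fractions per type within one scope."""

    scope: str
    counts: dict[str, int]
    fractions: dict[str, float] = field(init=False)
    total: int = field(init=False)

    def __post_init__(self) -> None:
        self.total = int(sum(self.counts.values()))
        if self.total == 0:
            raise ValueError(f"scope {self.scope!r} contains no cells")
        self.fractions = {t: c / self.total for t, c in self.counts.items()}

    def percent(self, cell_type: str, decimals: int = 1) -> float:
        """Percentage of scope cells of a type, rounded for reporting."""
        return format_percent(self.fractions[cell_type], decimals)


def format_percent(fraction: float, decimals: int = 1) -> float:
    """Report a fraction as a percentage rounded to ``decimals`` places."""
    return float(round(100.0 * fraction, decimals))


def format_fold(fold: float) -> str:
    """One-decimal fold string, '≈N-fold' at integer precision when close."""
    if abs(fold - round(fold)) < 0.5:
        return f"≈{round(fold):d}-fold"
    return f"{fold:.1f}-fold"


def composition(table: SpatialCellTable, scope: str = WHOLE
                ) -> CompositionSummary:
    """Count cells of each type within a scope and express as fractions."""
    mask = table.region_mask(scope)
    types, counts = np.unique(table.cell_type[mask], return_counts=True)
    return CompositionSummary(scope, {str(t): int(c)
                                      for t, c in zip(types, counts)})


def region_fold_enrichment(table: SpatialCellTable, region: str,
                           cell_type: str, reference: str = "whole_slide"
                           ) -> tuple[float, float, float]:
    """Fold enrichment of a type in a region vs a reference scope.

    ``reference="whole_slide"`` includes the region's own cells in the
    denominator; ``"remainder"`` excludes them. Returns
    (fold, region_fraction, reference_fraction).
    """
    if reference not in ("whole_slide", "remainder"):
        raise ValueError(f"unknown reference {reference!r}")
    rmask = table.region_mask(region)
    ref_mask = np.ones(table.n_cells, bool) if reference == "whole_slide" \
        else ~rmask
    if not ref_mask.any():
        raise ValueError("reference scope is empty")
    region_frac = float(np.mean(table.cell_type[rmask] == cell_type))
    ref_frac = float(np.mean(table.cell_type[ref_mask] == cell_type))
    if ref_frac == 0:
        raise ValueError(
            f"type {cell_type!r} absent from reference; fold undefined")
    return region_frac / ref_frac, region_frac, ref_frac


def detection_stats(table: SpatialCellTable, genes: list[str],
                    scope: str = WHOLE, positive_min: int = 1
                    ) -> pd.DataFrame:
    """Fraction of positive cells and mean count per (gene, cell type).

    Mean counts average over all scope cells of the type, zeros included.
    """
    missing = [g for g in genes if g not in table.genes]
    if missing:
        raise KeyError(f"gene(s) not in panel: {missing}")
    mask = table.region_mask(scope)
    rows = []
    types = sorted(set(table.cell_type[mask]))
    for gene in genes:
        col = table.gene_column(gene)[mask]
        ctypes = table.cell_type[mask]
        for t in types:
            tmask = ctypes == t
            vals = col[tmask]
            rows.append({
                "gene": gene, "cell_type": t, "n_cells": int(tmask.sum()),
                "fraction_positive": float(np.mean(vals >= positive_min)),
                "mean_count": float(np.mean(vals)),
            })
    return pd.DataFrame(rows)


def zoom_gene_enrichment(table: SpatialCellTable, region: str,
                         genes: list[str], positive_min: int = 1
                         ) -> pd.DataFrame:
    """Region-vs-remainder Fisher test of gene-positive fractions.

    Per gene: a 2x2 table of (positive, negative) x (region, remainder),
    two-sided Fisher's exact p, fold = positive-fraction ratio, BH q over
    the gene list. Genes with no positive cells anywhere get fold = NaN
    and p = 1.
    """
    missing = [g for g in genes if g not in table.genes]
    if missing:
        raise KeyError(f"gene(s) not in panel: {missing}")
    rmask = table.region_mask(region)
    omask = ~rmask
    if not omask.any():
        raise ValueError("remainder is empty")
    rows = []
    for gene in genes:
        pos = table.gene_column(gene) >= positive_min
        a, b = int((pos & rmask).sum()), int((~pos & rmask).sum())
        c, d = int((pos & omask).sum()), int((~pos & omask).sum())
        if a + c == 0:
            rows.append({"gene": gene, "pos_region": a, "pos_rest": c,
                         "fold": np.nan, "odds_ratio": np.nan, "p_value": 1.0})
            continue
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        in_frac = a / rmask.sum()
        out_frac = c / omask.sum()
        fold = in_frac / out_frac if out_frac > 0 else np.inf
        rows.append({"gene": gene, "pos_region": a, "pos_rest": c,
                     "fold": float(fold), "odds_ratio": float(odds),
                     "p_value": float(p)})
    df = pd.DataFrame(rows)
    df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    return df
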