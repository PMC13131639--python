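"""Synthetic cohort generators for bulk, single-cell and spatial data.

Each generator is a pure function of its parameter object (which carries
the seed), so identical parameters yield bit-identical outputs. Bulk
counts are negative-binomial, single-cell counts Poisson-lognormal, and
spatial transcript counts zero-inflated Poisson with per-type detection
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_core import ExpressionMatrix, SampleMetadata
from .markers import CellTable
from .spatial import SpatialCellTable

__all__ = [
    "BulkSimParams",
    "ScSimParams",
    "SpatialSimParams",
    "GenePanel",
    "simulate_bulk",
    "simulate_sc",
    "simulate_spatial",
    "SC_CELL_TYPES",
]

SC_CELL_TYPES = (
    "T", "B", "plasma", "myeloid", "endothelial",
    "lining_fibroblast", "sublining_fibroblast", "mural",
)


def _check_proportions(p, tol: float = 1e-9) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > tol:
        raise ValueError(f"proportions sum to {p.sum()}, not 1")
    return p


@dataclass(frozen=True)
class BulkSimParams:
    """Bulk cohort with planted cluster structure and shifted OARSI scores."""

    n_samples: int = 135
    cluster_proportions: tuple[float, ...] = (0.29, 0.38, 0.27, 0.06)
    n_genes: int = 2000
    markers_per_cluster: int = 100
    log2_effect: float = 2.0
    nb_dispersion: float = 0.15
    baseline_mean_log: float = 4.0
    oarsi_shift: dict[int, int] = field(
        default_factory=lambda: {1: 0, 2: 2, 3: 2, 4: 0})
    libsize_cv: float = 0.3
    oarsi_max: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        p = _check_proportions(self.cluster_proportions)
        if np.any(p <= 0):
            raise ValueError("every cluster needs positive proportion")
        k = len(p)
        if self.n_samples < 4 * k:
            raise ValueError(f"need n_samples >= {4 * k} for {k} clusters")
        if np.any(np.round(p * self.n_samples) < 1):
            raise ValueError("a cluster has zero expected samples")
        if self.markers_per_cluster * k > self.n_genes:
            raise ValueError("marker blocks exceed gene count")


def _cluster_sizes(proportions: np.ndarray, n: int) -> np.ndarray:
    # largest-remainder apportionment: deterministic, sums to n
    raw = proportions * n
    sizes = np.floor(raw).astype(int)
    rem = n - sizes.sum()
    order = np.argsort(-(raw - sizes))
    sizes[order[:rem]] += 1
    if np.any(sizes == 0):
        raise ValueError("a cluster received zero samples")
    return sizes


def simulate_bulk(params: BulkSimParams
                  ) -> tuple[ExpressionMatrix, SampleMetadata]:
    """Simulate a bulk cohort; metadata carries true cluster labels.

    Returns (raw-count matrix, metadata). Cluster k's marker block has its
    mean multiplied by 2**log2_effect in cluster-k samples. D-OARSI is an
    integer draw skewed toward the top of the 12-20 range plus a per-cluster
    shift, clipped to [0, oarsi_max]. A binary "major_trauma" covariate is
    elevated in the last cluster.
    """
    rng = np.random.default_rng(params.seed)
    p = np.asarray(params.cluster_proportions, dtype=float)
    k = len(p)
    sizes = _cluster_sizes(p, params.n_samples)
    labels = np.repeat(np.arange(1, k + 1), sizes)

    n_genes, n = params.n_genes, params.n_samples
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    sample_ids = [f"S{i:03d}" for i in range(n)]

    base_mean = rng.lognormal(mean=params.baseline_mean_log, sigma=1.0,
                              size=n_genes)
    libfac = rng.lognormal(mean=0.0,
                           sigma=np.sqrt(np.log(1 + params.libsize_cv ** 2)),
                           size=n)

    mean = np.outer(base_mean, libfac)
    marker_genes: dict[int, list[str]] = {}
    for c in range(k):
        lo = c * params.markers_per_cluster
        hi = lo + params.markers_per_cluster
        marker_genes[c + 1] = gene_ids[lo:hi]
        in_cluster = labels == c + 1
        mean[lo:hi, :][:, in_cluster] *= 2.0 ** params.log2_effect

    # NB via gamma-Poisson: shape r = 1/dispersion, scale mean/r
    r = 1.0 / params.nb_dispersion
    lam = rng.gamma(shape=r, scale=mean / r)
    counts = rng.poisson(lam).astype(float)
    matrix = ExpressionMatrix(gene_ids, sample_ids, counts, "raw_counts")

    # D-OARSI: integers 12-20 skewed high, plus per-cluster shift
    support = np.arange(12, 21)
    weights = np.arange(1, 10, dtype=float) ** 2
    weights /= weights.sum()
    base = rng.choice(support, size=n, p=weights)
    shift = np.array([params.oarsi_shift.get(int(c), 0) for c in labels])
    d_oarsi = np.clip(base + shift, 0, params.oarsi_max)

    control = rng.choice(np.arange(2, 13), size=n)
    kl = rng.choice([2, 3, 4], size=n, p=[0.1, 0.5, 0.4])
    trauma_rate = np.where(labels == k, 0.38, 0.10)
    trauma = (rng.random(n) < trauma_rate).astype(int)
    age = np.round(rng.normal(66, 6, size=n), 1)

    table = pd.DataFrame({
        "d_oarsi": d_oarsi,
        "control_oarsi": control,
        "kl_grade": kl,
        "cluster": [f"C{c}" for c in labels],
        "age": age,
        "major_trauma": np.where(trauma == 1, "yes", "no"),
    }, index=pd.Index(sample_ids, name="sample_id"))
    meta = SampleMetadata(table, {"age": "continuous",
                                  "major_trauma": "categorical"})
    meta.true_markers = marker_genes  # type: ignore[attr-defined]
    return matrix, meta


@dataclass(frozen=True)
class ScSimParams:
    """Single-cell dataset with planted per-type marker genes."""

    n_cells: int = 4000
    cell_type_proportions: tuple[float, ...] = (
        0.15, 0.06, 0.04, 0.30, 0.15, 0.08, 0.17, 0.05)
    cell_types: tuple[str, ...] = SC_CELL_TYPES
    n_genes: int = 1000
    markers_per_type: int = 20
    marker_fold: float = 8.0
    capture_rate: float = 1.0
    base_mean: float = 0.3
    libsize_sigma: float = 0.3
    embedding_dim: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        _check_proportions(self.cell_type_proportions)
        if len(self.cell_type_proportions) != len(self.cell_types):
            raise ValueError("proportions/types length mismatch")
        if not 0 < self.capture_rate <= 1:
            raise ValueError("capture_rate must be in (0, 1]")
        if self.marker_fold <= 0:
            raise ValueError("marker_fold must be positive")
        if self.markers_per_type * len(self.cell_types) > self.n_genes:
            raise ValueError("marker blocks exceed gene count")


def simulate_sc(params: ScSimParams) -> CellTable:
    """Simulate typed single cells with Poisson-lognormal counts.

    Marker block g for type t has mean multiplied by ``marker_fold`` in
    type-t cells; at the default fold and capture rate planted markers
    clear the downstream selection thresholds in expectation. The planted
    truth is attached as ``table.true_markers``.
    """
    rng = np.random.default_rng(params.seed)
    types = list(params.cell_types)
    p = np.asarray(params.cell_type_proportions, dtype=float)
    sizes = _cluster_sizes(p, params.n_cells)
    labels = np.repeat(np.arange(len(types)), sizes)

    n_cells, n_genes = params.n_cells, params.n_genes
    gene_ids = [f"SG{i:05d}" for i in range(n_genes)]
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]

    base = np.full(n_genes, params.base_mean)
    mean = np.tile(base, (n_cells, 1))
    true_markers: dict[str, list[str]] = {}
    for t, name in enumerate(types):
        lo = t * params.markers_per_type
        hi = lo + params.markers_per_type
        true_markers[name] = gene_ids[lo:hi]
        mean[labels == t, lo:hi] *= params.marker_fold

    # lognormal cell-level noise -> overdispersed (Poisson-lognormal)
    size_fac = rng.lognormal(0.0, params.libsize_sigma, size=n_cells)
    noise = rng.lognormal(-0.5 * 0.2 ** 2, 0.2, size=(n_cells, n_genes))
    lam = mean * noise * size_fac[:, None] * params.capture_rate
    counts = rng.poisson(lam)

    table = CellTable.from_counts(cell_ids, gene_ids, counts,
                                  [types[t] for t in labels],
                                  embedding_dim=params.embedding_dim)
    table.true_markers = true_markers  # type: ignore[attr-defined]
    return table


@dataclass(frozen=True)
class GenePanel:
    """In-situ panel: per-gene, per-type detection probability and mean count.

    ``detection[gene][cell_type]`` is the probability a cell of that type
    is positive for the gene; ``mean_extra[gene][cell_type]`` the Poisson
    mean of additional transcripts in positive cells.
    """

    genes: tuple[str, ...]
    detection: dict[str, dict[str, float]]
    mean_extra: dict[str, dict[str, float]]

    def prob(self, gene: str, cell_type: str) -> float:
        return self.detection.get(gene, {}).get(cell_type, 0.0)

    def extra(self, gene: str, cell_type: str) -> float:
        return self.mean_extra.get(gene, {}).get(cell_type, 0.0)


SPATIAL_CELL_TYPES = (
    "sublining_fibroblast", "lining_fibroblast", "dendritic", "macrophage",
    "endothelial", "mural", "adipocyte", "other",
)


def default_gene_panel() -> GenePanel:
    """Small default panel: one adipocyte gene, one uniform control."""
    det = {
        "ADIPO_MARKER": {t: (0.9 if t == "adipocyte" else 0.02)
                         for t in SPATIAL_CELL_TYPES},
        "CONTROL_GENE": {t: 0.30 for t in SPATIAL_CELL_TYPES},
    }
    extra = {
        "ADIPO_MARKER": {t: (1.5 if t == "adipocyte" else 0.1)
                         for t in SPATIAL_CELL_TYPES},
        "CONTROL_GENE": {t: 0.3 for t in SPATIAL_CELL_TYPES},
    }
    return GenePanel(("ADIPO_MARKER", "CONTROL_GENE"), det, extra)


@dataclass(frozen=True)
class SpatialSimParams:
    """Spatial slide with a rare type concentrated in one rectangle."""

    n_cells: int = 36320
    slide_extent: tuple[float, float] = (5000.0, 5000.0)
    type_proportions: dict[str, float] = field(default_factory=lambda: {
        "sublining_fibroblast": 0.301, "lining_fibroblast": 0.291,
        "dendritic": 0.155, "macrophage": 0.122, "endothelial": 0.063,
        "mural": 0.046, "adipocyte": 0.0023, "other": 0.0197})
    enriched_region: tuple[float, float, float, float] = (
        100.0, 100.0, 500.0, 500.0)  # x0, y0, x1, y1
    region_name: str = "zoom"
    enriched_type: str = "adipocyte"
    enriched_proportion: float = 0.0586
    gene_panel: GenePanel = field(default_factory=default_gene_panel)
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.array(list(self.type_proportions.values()))
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("type proportions must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("type proportions must sum to 1")
        x0, y0, x1, y1 = self.enriched_region
        w, h = self.slide_extent
        if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
            raise ValueError("enriched region must lie inside the slide")
        if self.enriched_type not in self.type_proportions:
            raise ValueError("enriched type missing from proportions")
        if not 0 <= self.enriched_proportion <= 1:
            raise ValueError("enriched proportion must lie in [0, 1]")


def simulate_spatial(params: SpatialSimParams) -> SpatialCellTable:
    """Simulate a positioned, typed cell table with transcript counts.

    Positions are uniform over the slide; cell types are multinomial with
    the enriched type's proportion overridden inside the region. Counts
    are zero-inflated Poisson per the panel's type-conditional rates.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_cells
    w, h = params.slide_extent
    x = rng.uniform(0, w, size=n)
    y = rng.uniform(0, h, size=n)
    x0, y0, x1, y1 = params.enriched_region
    inside = (x >= x0) & (x < x1) & (y >= y0) & (y < y1)

    types = list(params.type_proportions)
    base_p = np.array([params.type_proportions[t] for t in types])
    enr_p = base_p.copy()
    ei = types.index(params.enriched_type)
    enr_p[ei] = params.enriched_proportion
    other = np.delete(np.arange(len(types)), ei)
    rest = 1.0 - params.enriched_proportion
    base_rest = base_p[other].sum()
    enr_p[other] = base_p[other] * (rest / base_rest if base_rest > 0 else 0)

    type_idx = np.empty(n, dtype=int)
    type_idx[~inside] = rng.choice(len(types), size=int((~inside).sum()),
                                   p=base_p / base_p.sum())
    type_idx[inside] = rng.choice(len(types), size=int(inside.sum()),
                                  p=enr_p / enr_p.sum())
    cell_types = np.array(types, dtype=object)[type_idx]

    panel = params.gene_panel
    counts = np.zeros((n, len(panel.genes)), dtype=int)
    for j, gene in enumerate(panel.genes):
        probs = np.array([panel.prob(gene, t) for t in types])[type_idx]
        extra = np.array([panel.extra(gene, t) for t in types])[type_idx]
        detected = rng.random(n) < probs
        counts[detected, j] = 1 + rng.poisson(extra[detected])

    region = np.where(inside, params.region_name, "rest")
    return SpatialCellTable(
        cell_ids=[f"sp{i:05d}" for i in range(n)],
        x=x, y=y,
        cell_type=cell_types,
        region=region,
        genes=list(panel.genes),
        gene_counts=counts,
    )
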