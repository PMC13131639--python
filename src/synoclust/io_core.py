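"""Shared data containers and readers/writers for external formats.

Everything here is deterministic: expression matrices (dense CSV/TSV or
Matrix Market triplet), GMT gene-set collections, TSV sample metadata,
and logCPM normalization.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ExpressionMatrix",
    "SampleMetadata",
    "GeneSetCollection",
    "ParseError",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_metadata",
    "write_metadata",
    "log_cpm",
]

RAW_COUNTS = "raw_counts"
LOGCPM = "logcpm"


class ParseError(ValueError):
    """Raised on malformed input files; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


def _check_unique(ids: Iterable[str], kind: str) -> list[str]:
    ids = list(ids)
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ParseError(f"duplicate {kind} identifier: {i!r}")
        seen.add(i)
    return ids


@dataclass
class ExpressionMatrix:
    """Gene x sample numeric matrix with explicit layer semantics.

    ``layer`` is ``"raw_counts"`` (non-negative integers) or ``"logcpm"``
    (finite floats). Rows are genes, columns are samples.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    layer: str = RAW_COUNTS

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.layer not in (RAW_COUNTS, LOGCPM):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.layer == RAW_COUNTS:
            if np.any(self.values < 0):
                raise ValueError("raw counts must be non-negative")
            if not np.allclose(self.values, np.round(self.values)):
                raise ValueError("raw counts must be integers")
        else:
            if not np.all(np.isfinite(self.values)):
                raise ValueError("logcpm values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in matrix") from None

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(list(genes), list(self.sample_ids),
                                self.values[idx], self.layer)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.sample_ids)


@dataclass
class SampleMetadata:
    """Per-sample clinical/histologic annotations.

    ``table`` has one row per sample, indexed by sample_id, with reserved
    columns ``d_oarsi``, ``control_oarsi``, ``kl_grade``, ``cluster``; any
    other column is a clinical covariate whose type is declared in
    ``clinical_types`` ("continuous" or "categorical").
    """

    table: pd.DataFrame
    clinical_types: dict[str, str] = field(default_factory=dict)

    RESERVED = ("d_oarsi", "control_oarsi", "kl_grade", "cluster")

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        for col in ("d_oarsi", "control_oarsi"):
            if col in self.table.columns:
                vals = self.table[col].dropna()
                if (vals < 0).any():
                    raise ValueError(f"{col} must be non-negative")
        for name, kind in self.clinical_types.items():
            if kind not in ("continuous", "categorical"):
                raise ValueError(f"covariate {name!r}: unknown type {kind!r}")
            if name not in self.table.columns:
                raise ValueError(f"declared covariate {name!r} missing")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def aligned_to(self, matrix: ExpressionMatrix) -> "SampleMetadata":
        """Reorder rows to match a matrix; every sample must be present."""
        missing = set(matrix.sample_ids) - set(self.table.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")
        return SampleMetadata(self.table.loc[matrix.sample_ids],
                              dict(self.clinical_types))


@dataclass
class GeneSetCollection:
    """Named gene sets (deduplicated, non-empty) with a source tag."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        cleaned: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            deduped = list(dict.fromkeys(genes))
            if not deduped:
                raise ValueError(f"gene set {name!r} is empty")
            cleaned[name] = deduped
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# Expression matrix I/O
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, format: str = "dense_csv", *,
                    sep: str | None = None, layer: str = RAW_COUNTS,
                    transpose: bool = False) -> ExpressionMatrix:
    """Read an expression matrix.

    dense_csv: first column gene id, header row of sample ids (genes in
    rows unless ``transpose``). mtx_triplet: ``path`` is the .mtx file with
    companion ``<stem>.genes.txt`` and ``<stem>.samples.txt`` id files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "dense_csv":
        return _read_dense(path, sep=sep, layer=layer, transpose=transpose)
    if format == "mtx_triplet":
        return _read_mtx(path, layer=layer)
    raise ValueError(f"unknown format {format!r}")


def _read_dense(path: Path, *, sep: str | None, layer: str,
                transpose: bool) -> ExpressionMatrix:
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].strip():
        raise ParseError("empty or malformed header", line=1)
    header = lines[0].split(sep)
    sample_ids = [h.strip() for h in header[1:]]
    if not sample_ids:
        raise ParseError("header contains no sample identifiers", line=1)
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        parts = raw.split(sep)
        if len(parts) != len(header):
            raise ParseError(
                f"expected {len(header)} fields, found {len(parts)}",
                line=lineno)
        gene_ids.append(parts[0].strip())
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError:
            bad = next(v for v in parts[1:] if not _is_number(v))
            raise ParseError(f"non-numeric value {bad.strip()!r}", line=lineno)
    try:
        _check_unique(gene_ids, "gene")
        _check_unique(sample_ids, "sample")
    except ParseError as exc:
        raise ParseError(str(exc)) from None
    values = np.array(rows, dtype=float).reshape(len(gene_ids), len(sample_ids))
    if transpose:
        values = values.T
        gene_ids, sample_ids = sample_ids, gene_ids
    return ExpressionMatrix(gene_ids, sample_ids, values, layer)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _read_mtx(path: Path, *, layer: str) -> ExpressionMatrix:
    stem = path.with_suffix("")
    gene_file = Path(str(stem) + ".genes.txt")
    sample_file = Path(str(stem) + ".samples.txt")
    for f in (gene_file, sample_file):
        if not f.exists():
            raise FileNotFoundError(f"companion identifier file missing: {f}")
    gene_ids = gene_file.read_text(encoding="utf-8").split()
    sample_ids = sample_file.read_text(encoding="utf-8").split()
    try:
        mat = scipy.io.mmread(str(path))
    except Exception as exc:  # scipy raises bare ValueError on bad files
        raise ParseError(f"malformed MTX file: {exc}") from exc
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat,
                       dtype=float)
    if dense.shape != (len(gene_ids), len(sample_ids)):
        raise ParseError(
            f"MTX dimensions {dense.shape} do not match identifier files "
            f"({len(gene_ids)} genes, {len(sample_ids)} samples)")
    return ExpressionMatrix(gene_ids, sample_ids, dense, layer)


def write_expression(matrix: ExpressionMatrix, path: str | Path, *,
                     sep: str | None = None) -> None:
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id" + sep + sep.join(matrix.sample_ids) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gid + sep + sep.join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, source: str = "") -> GeneSetCollection:
    """Parse a GMT file: tab-separated name, description, gene symbols."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(),
                                 start=1):
        if not raw.strip():
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(
                f"GMT line needs name, description and >=1 gene "
                f"({len(parts)} fields found)", line=lineno)
        name = parts[0]
        if name in sets:
            raise ParseError(f"duplicate set name {name!r}", line=lineno)
        genes = [g for g in parts[2:] if g.strip()]
        if not genes:
            raise ParseError(f"set {name!r} has no genes", line=lineno)
        sets[name] = genes
    return GeneSetCollection(sets, source or str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# Metadata TSV
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path,
                  clinical_types: Mapping[str, str] | None = None
                  ) -> SampleMetadata:
    """Read sample metadata TSV. Missing values are empty cells.

    Covariate types default to continuous when the column parses numeric,
    categorical otherwise; explicit ``clinical_types`` overrides.
    """
    df = pd.read_csv(path, sep="\t", index_col="sample_id", dtype=str)
    out = pd.DataFrame(index=df.index)
    types: dict[str, str] = {}
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        declared = (clinical_types or {}).get(col)
        is_numeric = numeric.notna().sum() == df[col].notna().sum()
        if declared == "categorical" or (declared is None and not is_numeric):
            out[col] = df[col]
            if col not in SampleMetadata.RESERVED:
                types[col] = "categorical"
        else:
            out[col] = numeric
            if col not in SampleMetadata.RESERVED:
                types[col] = "continuous"
    return SampleMetadata(out, types)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def log_cpm(matrix: ExpressionMatrix, pseudocount: float = 1.0
            ) -> ExpressionMatrix:
    """log2(1e6 * count / library_size + pseudocount), per sample.

    With the default pseudocount of 1, zero counts map to exactly 0.
    """
    if matrix.layer != RAW_COUNTS:
        raise ValueError("log_cpm expects a raw_counts matrix")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    lib = matrix.values.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        names = [matrix.sample_ids[i] for i in zero]
        raise ValueError(f"zero library size for sample(s): {names}")
    values = np.log2(1e6 * matrix.values / lib + pseudocount)
    return ExpressionMatrix(list(matrix.gene_ids), list(matrix.sample_ids),
                            values, LOGCPM)
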