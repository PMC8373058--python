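"""Reading, quality control, and formatting of expression matrices.

All datasets — references and queries alike — are brought into one
identical format before any learning happens: cells that fail quality
control are dropped, rare cell types are removed from references, counts
are depth-normalized and log-transformed, and every matrix is projected
onto the union of the reference gene sets (missing genes zero-filled) so
that a single network can embed cells from any batch.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import (
    DegenerateCellError,
    DimensionError,
    EmptyDatasetError,
    ParseError,
)

__all__ = [
    "AnnotatedDataset",
    "QCThresholds",
    "GeneUnion",
    "read_matrix",
    "read_labels",
    "attach_labels",
    "qc_filter",
    "filter_rare_types",
    "normalize",
    "build_gene_union",
    "align_to_union",
    "write_dataset",
]


@dataclasses.dataclass
class AnnotatedDataset:
    """A cells x genes expression matrix with optional per-cell labels.

    ``matrix`` holds raw counts while ``normalized`` is False and
    depth-normalized log values afterwards. Rows align with ``cell_ids``,
    columns with ``gene_ids``; ``labels``, when present, gives one
    cell-type string per cell.
    """

    name: str
    matrix: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    labels: list[str] | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise DimensionError(f"{self.name}: matrix must be 2-D")
        n_cells, n_genes = self.matrix.shape
        if len(self.cell_ids) != n_cells:
            raise DimensionError(
                f"{self.name}: {len(self.cell_ids)} cell ids for {n_cells} rows"
            )
        if len(self.gene_ids) != n_genes:
            raise DimensionError(
                f"{self.name}: {len(self.gene_ids)} gene ids for {n_genes} columns"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise DimensionError(f"{self.name}: duplicate cell ids")
        if len(set(self.gene_ids)) != n_genes:
            raise DimensionError(f"{self.name}: duplicate gene ids")
        if np.any(self.matrix < 0):
            raise DimensionError(f"{self.name}: negative expression values")
        if not self.normalized and not np.all(self.matrix == np.round(self.matrix)):
            raise DimensionError(f"{self.name}: raw counts must be integers")
        if self.labels is not None and len(self.labels) != n_cells:
            raise DimensionError(
                f"{self.name}: {len(self.labels)} labels for {n_cells} cells"
            )

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def subset_cells(self, keep: np.ndarray) -> "AnnotatedDataset":
        """Return a copy restricted to the boolean/index mask ``keep``."""
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return AnnotatedDataset(
            name=self.name,
            matrix=self.matrix[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            labels=None if self.labels is None else [self.labels[i] for i in idx],
            normalized=self.normalized,
        )


@dataclasses.dataclass(frozen=True)
class QCThresholds:
    """Cell quality-control cutoffs; all three comparisons are strict.

    A cell is retained only if it has more than ``min_genes_detected``
    genes with nonzero counts, more than ``min_umi`` total counts, and a
    mitochondrial count fraction strictly below ``max_mito_fraction``.
    Mitochondrial genes are recognized by a case-insensitive identifier
    prefix (human/mouse convention ``MT-``).
    """

    min_genes_detected: int = 500
    min_umi: int = 1500
    max_mito_fraction: float = 0.10
    mito_gene_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_genes_detected < 0 or self.min_umi < 0:
            raise ValueError("QC count thresholds must be non-negative")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0, 1]")


@dataclasses.dataclass(frozen=True)
class GeneUnion:
    """Ordered (lexicographically sorted) union of reference gene ids."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise DimensionError("gene union contains duplicates")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


def _collapse_duplicate_genes(
    matrix: np.ndarray, gene_ids: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Sum columns that share a gene identifier (first occurrence order)."""
    if len(set(gene_ids)) == len(gene_ids):
        return matrix, gene_ids
    order: dict[str, int] = {}
    for g in gene_ids:
        order.setdefault(g, len(order))
    out = np.zeros((matrix.shape[0], len(order)), dtype=matrix.dtype)
    for j, g in enumerate(gene_ids):
        out[:, order[g]] += matrix[:, j]
    return out, list(order)


def _read_delimited(path: Path, name: str) -> AnnotatedDataset:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
    # header parsed by hand so duplicate gene ids survive un-mangled
    gene_names = [g for g in header.split(sep)[1:]]
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, skiprows=1, header=None)
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: cannot parse delimited matrix: {exc}") from exc
    if df.shape[1] != len(gene_names):
        raise ParseError(f"{path}: header has {len(gene_names)} genes but data "
                         f"rows have {df.shape[1]} fields")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=np.float64)
    if np.isnan(values).any():
        row = int(np.flatnonzero(np.isnan(values).any(axis=1))[0])
        raise ParseError(
            f"{path}: non-numeric value on data line {row + 2} "
            f"(cell {df.index[row]!r})"
        )
    matrix, gene_ids = _collapse_duplicate_genes(values, [str(g) for g in gene_names])
    return AnnotatedDataset(
        name=name,
        matrix=matrix,
        cell_ids=[str(c) for c in df.index],
        gene_ids=gene_ids,
        normalized=False,
    )


def _read_sidecar(path: Path) -> list[str]:
    """One identifier per line; extra tab-separated fields ignored."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                out.append(line.split("\t")[0])
    return out


def _find_sidecar(mtx_path: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for ext in (".tsv", ".txt"):
            cand = mtx_path.parent / f"{stem}{ext}"
            if cand.exists():
                return cand
    raise ParseError(
        f"{mtx_path}: missing sidecar file (looked for {', '.join(stems)})"
    )


def _read_matrix_market(path: Path, name: str) -> AnnotatedDataset:
    try:
        mat = scipy.io.mmread(path)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse MatrixMarket file: {exc}") from exc
    mat = np.asarray(
        mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=np.float64
    )
    barcodes = _read_sidecar(_find_sidecar(path, ("barcodes",)))
    features = _read_sidecar(_find_sidecar(path, ("features", "genes")))
    # On-disk convention is genes-as-rows; transpose to cells x genes. If the
    # orientation is already cells x genes, accept it as-is.
    if mat.shape == (len(features), len(barcodes)):
        mat = mat.T
    elif mat.shape != (len(barcodes), len(features)):
        raise DimensionError(
            f"{path}: matrix shape {mat.shape} matches neither "
            f"({len(features)} features x {len(barcodes)} barcodes) nor its transpose"
        )
    matrix, gene_ids = _collapse_duplicate_genes(mat, features)
    return AnnotatedDataset(
        name=name, matrix=matrix, cell_ids=barcodes, gene_ids=gene_ids,
        normalized=False,
    )


def read_matrix(path: str | Path, format: str = "delimited",
                name: str | None = None) -> AnnotatedDataset:
    """Read an expression matrix from disk as raw counts.

    ``format`` is ``"delimited"`` (TSV/CSV; first row gene ids, first
    column cell ids) or ``"matrix_market"`` (coordinate ``.mtx`` with
    ``barcodes`` and ``features``/``genes`` text sidecars, genes as rows
    on disk). Duplicate gene identifiers are collapsed by summing counts.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    if name is None:
        name = path.stem.removesuffix(".mtx")
    if format == "delimited":
        return _read_delimited(path, name)
    if format == "matrix_market":
        return _read_matrix_market(path, name)
    raise ValueError(f"unknown format {format!r}")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column (cell_id, cell_type) TSV; header row optional."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    labels: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            cell, ctype = fields
            if lineno == 1 and cell.strip().lower() in {"cell_id", "cell", "barcode"}:
                continue  # header
            if cell in labels:
                raise ParseError(f"{path}: line {lineno}: duplicate cell id {cell!r}")
            labels[cell] = ctype
    return labels


def attach_labels(ds: AnnotatedDataset, labels: dict[str, str]) -> AnnotatedDataset:
    """Attach a label to every cell; each cell must appear exactly once."""
    missing = [c for c in ds.cell_ids if c not in labels]
    if missing:
        raise DimensionError(
            f"{ds.name}: {len(missing)} cells missing from label table "
            f"(first: {missing[0]!r})"
        )
    return dataclasses.replace(ds, labels=[labels[c] for c in ds.cell_ids])


def qc_filter(ds: AnnotatedDataset, thr: QCThresholds = QCThresholds()) -> AnnotatedDataset:
    """Remove low-quality cells from a raw-count dataset.

    All three criteria are strict: genes detected > ``min_genes_detected``,
    total counts > ``min_umi``, mitochondrial fraction < ``max_mito_fraction``.
    """
    if ds.normalized:
        raise ValueError(f"{ds.name}: QC must run on raw counts")
    genes_detected = np.count_nonzero(ds.matrix, axis=1)
    total = ds.matrix.sum(axis=1)
    prefix = thr.mito_gene_prefix.upper()
    mito_cols = np.array(
        [g.upper().startswith(prefix) for g in ds.gene_ids], dtype=bool
    )
    mito = ds.matrix[:, mito_cols].sum(axis=1) if mito_cols.any() else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1e-300), 1.0)
    keep = (
        (genes_detected > thr.min_genes_detected)
        & (total > thr.min_umi)
        & (mito_frac < thr.max_mito_fraction)
    )
    if not keep.any():
        raise EmptyDatasetError(f"{ds.name}: quality control removed every cell")
    return ds.subset_cells(keep)


def filter_rare_types(ds: AnnotatedDataset, min_cells: int = 10) -> AnnotatedDataset:
    """Drop cells of types with fewer than ``min_cells`` cells."""
    if ds.labels is None:
        raise ValueError(f"{ds.name}: rare-type filtering needs labels")
    counts = pd.Series(ds.labels).value_counts()
    keep_types = set(counts.index[counts >= min_cells])
    if not keep_types:
        raise EmptyDatasetError(
            f"{ds.name}: no cell type has >= {min_cells} cells"
        )
    keep = np.array([lab in keep_types for lab in ds.labels], dtype=bool)
    return ds.subset_cells(keep)


def normalize(ds: AnnotatedDataset, scale: float = 10_000.0) -> AnnotatedDataset:
    """Depth-normalize to ``scale`` counts per cell and log-transform.

    Each cell's counts are divided by its total, multiplied by ``scale``,
    then mapped through the natural log of (value + 1).
    """
    if ds.normalized:
        raise ValueError(f"{ds.name}: already normalized")
    total = ds.matrix.sum(axis=1)
    if np.any(total == 0):
        bad = ds.cell_ids[int(np.flatnonzero(total == 0)[0])]
        raise DegenerateCellError(
            f"{ds.name}: cell {bad!r} has zero total counts"
        )
    values = np.log1p(ds.matrix / total[:, None] * scale)
    return dataclasses.replace(ds, matrix=values, normalized=True)


def build_gene_union(refs: Sequence[AnnotatedDataset]) -> GeneUnion:
    """Lexicographically sorted union of gene ids across references."""
    if not refs:
        raise ValueError("need at least one reference dataset")
    genes: set[str] = set()
    for ds in refs:
        genes.update(ds.gene_ids)
    return GeneUnion(genes=tuple(sorted(genes)))


def align_to_union(ds: AnnotatedDataset, union: GeneUnion) -> AnnotatedDataset:
    """Project onto the union feature space; absent genes become zeros.

    Genes of ``ds`` that are not in the union are dropped — the feature
    space is frozen when the union is built.
    """
    if not ds.normalized:
        raise ValueError(f"{ds.name}: align after normalization")
    col = {g: j for j, g in enumerate(ds.gene_ids)}
    out = np.zeros((ds.n_cells, len(union)), dtype=np.float64)
    for j, g in enumerate(union.genes):
        if g in col:
            out[:, j] = ds.matrix[:, col[g]]
    return dataclasses.replace(ds, matrix=out, gene_ids=list(union.genes))


def write_dataset(ds: AnnotatedDataset, matrix_path: str | Path,
                  labels_path: str | Path | None = None) -> None:
    """Write a dataset as a delimited matrix (+ optional label TSV)."""
    matrix_path = Path(matrix_path)
    sep = "," if matrix_path.suffix.lower() == ".csv" else "\t"
    values = ds.matrix
    if not ds.normalized:
        values = values.astype(np.int64)
    pd.DataFrame(values, index=ds.cell_ids, columns=ds.gene_ids).to_csv(
        matrix_path, sep=sep
    )
    if labels_path is not None:
        if ds.labels is None:
            raise ValueError(f"{ds.name}: no labels to write")
        pd.DataFrame({"cell_id": ds.cell_ids, "cell_type": ds.labels}).to_csv(
            labels_path, sep="\t", index=False
        )
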