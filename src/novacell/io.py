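"""Reading and writing expression matrices, label tables and annotation output.

On-disk conventions follow the 10x ecosystem: genes are rows, cells are
columns, and sparse matrices travel as a MatrixMarket triplet directory
(``matrix.mtx`` + ``features.tsv``/``genes.tsv`` + ``barcodes.tsv``, each
optionally gzipped). Dense matrices travel as CSV/TSV with a header row of
cell barcodes. Internally the same genes-by-cells orientation is kept.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

Matrix = Union[np.ndarray, sp.spmatrix]


class ValidationError(ValueError):
    """Input data violates a structural invariant (duplicates, negatives...)."""


def _duplicates(items) -> list:
    seen, dups = set(), []
    for x in items:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


@dataclass
class ExpressionMatrix:
    """Gene-by-cell non-negative count matrix with identifiers and a batch tag.

    ``counts`` may be dense or scipy-sparse; shape is (n_genes, n_cells).
    ``batch`` tags the whole matrix as "reference" or "query".
    """

    counts: Matrix
    gene_ids: list[str]
    cell_ids: list[str]
    batch: str = "reference"

    def __post_init__(self):
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        n_genes, n_cells = self.counts.shape
        if n_genes != len(self.gene_ids) or n_cells != len(self.cell_ids):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            dups = _duplicates(ids)
            if dups:
                raise ValidationError(f"duplicate {name} IDs: {dups[:10]}")
        mn = self.counts.min() if sp.issparse(self.counts) else np.min(self.counts) if self.counts.size else 0
        if self.counts.size and mn < 0:
            raise ValidationError("counts contain negative entries")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        idx = pd.Index(self.gene_ids).get_indexer(gene_ids)
        if (idx < 0).any():
            missing = [g for g, i in zip(gene_ids, idx) if i < 0]
            raise KeyError(f"genes not present: {missing[:10]}")
        counts = self.counts[idx, :] if not sp.issparse(self.counts) else self.counts.tocsr()[idx, :]
        return ExpressionMatrix(counts, list(gene_ids), list(self.cell_ids), self.batch)

    def subset_cells(self, cell_ids: list[str]) -> "ExpressionMatrix":
        idx = pd.Index(self.cell_ids).get_indexer(cell_ids)
        if (idx < 0).any():
            missing = [c for c, i in zip(cell_ids, idx) if i < 0]
            raise KeyError(f"cells not present: {missing[:10]}")
        counts = self.counts[:, idx] if not sp.issparse(self.counts) else self.counts.tocsc()[:, idx]
        return ExpressionMatrix(counts, list(self.gene_ids), list(cell_ids), self.batch)

    def dense(self) -> np.ndarray:
        return self.counts.toarray() if sp.issparse(self.counts) else np.asarray(self.counts)


@dataclass
class LabelTable:
    """cell_id -> cell-type label mapping for the reference set."""

    cell_ids: list[str]
    labels: list[str]

    def __post_init__(self):
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.labels = [str(l).strip() for l in self.labels]
        dups = _duplicates(self.cell_ids)
        if dups:
            raise ValidationError(f"duplicate cell IDs in label table: {dups[:10]}")
        if any(l == "" for l in self.labels):
            raise ValidationError("empty labels in label table")

    def __len__(self) -> int:
        return len(self.cell_ids)

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.cell_ids, name="label")


def _open_maybe_gz(path: Path):
    return gzip.open(path, "rt") if path.suffix == ".gz" else open(path)


def _find_triplet_file(d: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = d / name
            if p.exists():
                return p
    raise FileNotFoundError(f"none of {stems} (or .gz) found in {d}")


def read_counts(path, format: str = "mtx_dir", batch: str = "reference") -> ExpressionMatrix:
    """Read a gene-by-cell count matrix.

    ``format="mtx_dir"``: *path* is a 10x-style directory with matrix.mtx,
    features.tsv (or genes.tsv) and barcodes.tsv, each optionally gzipped.
    ``format="csv_dense"``: *path* is a CSV/TSV with genes as rows, cells as
    columns and a header row of cell IDs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input path does not exist: {path}")
    if format == "mtx_dir":
        mtx = _find_triplet_file(path, ("matrix.mtx",))
        feat = _find_triplet_file(path, ("features.tsv", "genes.tsv"))
        bar = _find_triplet_file(path, ("barcodes.tsv",))
        counts = scipy.io.mmread(str(mtx)).tocsr()
        with _open_maybe_gz(feat) as fh:
            gene_ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
        with _open_maybe_gz(bar) as fh:
            cell_ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
        return ExpressionMatrix(counts, gene_ids, cell_ids, batch)
    if format == "csv_dense":
        sep = "\t" if path.suffix in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        return ExpressionMatrix(df.to_numpy(dtype=float), list(df.index), list(df.columns), batch)
    raise ValueError(f"unknown format: {format!r} (expected 'mtx_dir' or 'csv_dense')")


def write_counts_csv(matrix: ExpressionMatrix, path) -> None:
    """Dense CSV writer (genes x cells); inverse of read_counts(format='csv_dense')."""
    df = pd.DataFrame(matrix.dense(), index=matrix.gene_ids, columns=matrix.cell_ids)
    df.to_csv(path)


def write_counts_mtx(matrix: ExpressionMatrix, path) -> None:
    """Write a 10x-style MTX triplet directory."""
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    counts = matrix.counts if sp.issparse(matrix.counts) else sp.csr_matrix(matrix.counts)
    scipy.io.mmwrite(str(d / "matrix.mtx"), sp.coo_matrix(counts))
    (d / "features.tsv").write_text("".join(f"{g}\t{g}\n" for g in matrix.gene_ids))
    (d / "barcodes.tsv").write_text("".join(f"{c}\n" for c in matrix.cell_ids))


def read_labels(path) -> LabelTable:
    """Read a two-column (cell_id, label) CSV with a header row."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label file does not exist: {path}")
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"label file needs 2 columns (cell_id,label), got {df.shape[1]}")
    cell_ids = df.iloc[:, 0].astype(str).str.strip().tolist()
    labels = df.iloc[:, 1].fillna("").astype(str).tolist()
    return LabelTable(cell_ids, labels)


def write_labels(table: LabelTable, path) -> None:
    pd.DataFrame({"cell_id": table.cell_ids, "label": table.labels}).to_csv(path, index=False)


def align_labels(matrix: ExpressionMatrix, table: LabelTable) -> tuple[ExpressionMatrix, LabelTable]:
    """Restrict a reference matrix to labeled cells.

    Cells without a label row are dropped with a warning (tolerant ingestion);
    label rows for cells absent from the matrix are ignored likewise.
    """
    have = set(table.cell_ids)
    keep = [c for c in matrix.cell_ids if c in have]
    n_drop = matrix.n_cells - len(keep)
    if n_drop:
        logger.warning("%d reference cells have no label and are excluded from training", n_drop)
    if not keep:
        raise ValidationError("no reference cell has a label")
    lab = table.as_series().loc[keep]
    return matrix.subset_cells(keep), LabelTable(keep, lab.tolist())


ANNOTATION_COLUMNS = ["cell_id", "final_label", "classifier_label", "max_probability", "cluster_id", "confident"]


def write_annotation(result, path, metadata: dict | None = None) -> None:
    """Write the per-cell annotation CSV plus a sidecar JSON of run metadata.

    *result* is an ``AnnotationResult`` (see :mod:`novacell.annotate`). The
    sidecar lands next to the CSV as ``<stem>.meta.json`` and always records
    the selected confidence threshold.
    """
    path = Path(path)
    df = result.to_frame()
    df.to_csv(path, index=False, float_format="%.10g")
    meta = dict(metadata or {})
    meta.setdefault("threshold", float(result.threshold.threshold))
    meta.setdefault("threshold_fallback_used", bool(result.threshold.fallback_used))
    meta.setdefault("n_reference_classes", int(result.threshold.K))
    sidecar = path.with_suffix(".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cell_id": str, "final_label": str, "classifier_label": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"annotation CSV missing columns: {missing}")
    return df
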