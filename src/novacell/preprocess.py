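"""Gene intersection, normalization, highly-variable-gene selection and PCA.

The reference and query matrices are first restricted to their shared genes,
then library-size normalized (counts per ``scale_factor``, log1p). Highly
variable genes are chosen on the combined data by standardized variance under
a fitted mean-variance trend, computed on the raw-count scale; the top PCs of
the z-scored HVG matrix seed the downstream batch correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import svds

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

MIN_SHARED_GENES = 200


@dataclass
class CombinedData:
    """Reference + query cells over a shared gene set.

    Carries both the raw counts (HVG selection operates on the count scale)
    and the log-normalized values (PCA operates on those), genes x cells.
    """

    counts: sp.csr_matrix
    values: np.ndarray | sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    batch: np.ndarray  # per-cell, "reference" | "query"

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class PCEmbedding:
    """Per-cell scores on the top principal components of the scaled HVG matrix."""

    scores: np.ndarray  # cells x n_pcs
    explained_variance: np.ndarray  # non-increasing
    n_pcs: int


def intersect_genes(
    ref: ExpressionMatrix, query: ExpressionMatrix, min_genes: int = MIN_SHARED_GENES
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to the sorted intersection of their gene sets."""
    shared = sorted(set(ref.gene_ids) & set(query.gene_ids))
    if len(shared) < min_genes:
        raise ValueError(
            f"insufficient shared genes: {len(shared)} < {min_genes} between reference and query"
        )
    return ref.subset_genes(shared), query.subset_genes(shared)


def _libsizes(counts) -> np.ndarray:
    s = counts.sum(axis=0)
    return np.asarray(s).ravel().astype(float)


def normalize(matrix: ExpressionMatrix, scale_factor: float = 1e4) -> ExpressionMatrix:
    """Library-size normalize and log-transform: log1p(count / libsize * scale_factor).

    Cells with zero total counts are dropped with a warning. Returns an
    ExpressionMatrix whose ``counts`` field holds the normalized values
    (still genes x cells, still non-negative).
    """
    if scale_factor <= 0:
        raise ValueError(f"scale_factor must be positive, got {scale_factor}")
    lib = _libsizes(matrix.counts)
    keep = lib > 0
    if not keep.all():
        logger.warning("dropping %d zero-count cells during normalization", int((~keep).sum()))
        matrix = matrix.subset_cells([c for c, k in zip(matrix.cell_ids, keep) if k])
        lib = lib[keep]
    if sp.issparse(matrix.counts):
        norm = matrix.counts.tocsc().astype(float)
        norm = norm.multiply(scale_factor / lib[None, :]).tocsr()
        norm.data = np.log1p(norm.data)
    else:
        norm = np.log1p(matrix.counts.astype(float) / lib[None, :] * scale_factor)
    return ExpressionMatrix(norm, matrix.gene_ids, matrix.cell_ids, matrix.batch)


def combine(ref_counts: ExpressionMatrix, query_counts: ExpressionMatrix,
            ref_norm: ExpressionMatrix, query_norm: ExpressionMatrix) -> CombinedData:
    """Column-concatenate reference and query (genes already intersected).

    Cells dropped during normalization (zero library size) are dropped from
    the raw side too, so both blocks stay column-aligned.
    """
    if ref_counts.gene_ids != query_counts.gene_ids:
        raise ValueError("reference and query gene sets differ; run intersect_genes first")
    ref_counts = ref_counts.subset_cells(ref_norm.cell_ids)
    query_counts = query_counts.subset_cells(query_norm.cell_ids)
    counts = sp.hstack(
        [sp.csr_matrix(ref_counts.counts), sp.csr_matrix(query_counts.counts)], format="csr"
    )
    if sp.issparse(ref_norm.counts) and sp.issparse(query_norm.counts):
        values = sp.hstack([ref_norm.counts, query_norm.counts], format="csr")
    else:
        values = np.hstack([ref_norm.dense(), query_norm.dense()])
    cell_ids = list(ref_norm.cell_ids) + list(query_norm.cell_ids)
    batch = np.array(["reference"] * len(ref_norm.cell_ids) + ["query"] * len(query_norm.cell_ids))
    return CombinedData(counts, values, list(ref_counts.gene_ids), cell_ids, batch)


def _row_mean_var(counts) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean and unbiased variance on the raw-count scale."""
    n = counts.shape[1]
    if sp.issparse(counts):
        mean = np.asarray(counts.mean(axis=1)).ravel()
        sq = np.asarray(counts.multiply(counts).mean(axis=1)).ravel()
    else:
        arr = np.asarray(counts, dtype=float)
        mean = arr.mean(axis=1)
        sq = (arr ** 2).mean(axis=1)
    var = (sq - mean ** 2) * n / max(n - 1, 1)
    return mean, np.maximum(var, 0.0)


def standardized_variances(counts) -> np.ndarray:
    """vst-style standardized variance per gene.

    A degree-2 polynomial trend of log10(variance) on log10(mean) predicts the
    expected variance of each gene; counts are standardized against it with
    values clipped at sqrt(n_cells) standard deviations, and the variance of
    the clipped z-scores is the gene's score. Genes with zero variance score 0.
    """
    n_cells = counts.shape[1]
    mean, var = _row_mean_var(counts)
    score = np.zeros(counts.shape[0])
    fit_mask = (mean > 0) & (var > 0)
    if fit_mask.sum() < 3:
        score[fit_mask] = var[fit_mask]
        return score
    lx, ly = np.log10(mean[fit_mask]), np.log10(var[fit_mask])
    coef = np.polyfit(lx, ly, deg=min(2, fit_mask.sum() - 1))
    exp_sd = np.sqrt(10 ** np.polyval(coef, lx))
    clip = np.sqrt(n_cells)
    dense = counts[np.flatnonzero(fit_mask), :]
    dense = dense.toarray() if sp.issparse(dense) else np.asarray(dense, dtype=float)
    z = (dense - mean[fit_mask][:, None]) / exp_sd[:, None]
    np.clip(z, -clip, clip, out=z)
    zc = z - z.mean(axis=1, keepdims=True)
    score[fit_mask] = (zc ** 2).sum(axis=1) / max(n_cells - 1, 1)
    return score


def select_hvgs(combined: CombinedData, n_hvg: int = 2000) -> list[str]:
    """Top *n_hvg* genes by standardized variance; score desc, gene_id asc on ties."""
    if n_hvg > len(combined.gene_ids):
        raise ValueError(f"n_hvg={n_hvg} exceeds number of genes {len(combined.gene_ids)}")
    score = standardized_variances(combined.counts)
    usable = int((score > 0).sum())
    if usable < n_hvg:
        logger.warning("only %d genes have nonzero standardized variance (requested %d)", usable, n_hvg)
        n_hvg = usable
    order = sorted(range(len(score)), key=lambda i: (-score[i], combined.gene_ids[i]))
    return [combined.gene_ids[i] for i in order[:n_hvg]]


def pca_embed(
    combined: CombinedData, hvgs: list[str], n_pcs: int = 50, seed: int = 0, z_clip: float = 10.0
) -> PCEmbedding:
    """Cells x n_pcs scores from truncated SVD of the z-scored HVG matrix.

    Each HVG is z-scored across cells (clipped at +/- *z_clip*) before the
    SVD. Component signs are fixed by making the largest-magnitude gene
    loading of each component positive, so the embedding is reproducible.
    """
    idx = [combined.gene_ids.index(g) for g in hvgs]
    vals = combined.values[idx, :]
    vals = vals.toarray() if sp.issparse(vals) else np.asarray(vals, dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = np.clip((vals - mu) / sd, -z_clip, z_clip)
    z -= z.mean(axis=1, keepdims=True)  # re-center after clipping
    x = z.T  # cells x genes
    rank = min(x.shape)
    if n_pcs > rank - 1:
        logger.warning("n_pcs=%d exceeds usable rank; reduced to %d", n_pcs, max(rank - 1, 1))
        n_pcs = max(rank - 1, 1)
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(min(x.shape))
    u, s, vt = svds(x, k=n_pcs, v0=v0)
    order = np.argsort(s)[::-1]
    u, s, vt = u[:, order], s[order], vt[order, :]
    # deterministic sign: largest-|.| loading of each component positive
    flip = np.sign(vt[np.arange(n_pcs), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    scores = u * s[None, :] * flip[None, :]
    explained = (s ** 2) / max(x.shape[0] - 1, 1)
    return PCEmbedding(scores=scores, explained_variance=explained, n_pcs=n_pcs)
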