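"""Batch correction in PC space, 2-D nonlinear embedding, and density clustering.

This is the unsupervised half of the pipeline: the reference and query cells
are aligned in the 50-D PC space, compressed to two dimensions with UMAP, and
grouped with DBSCAN. DBSCAN can leave cells unassigned (label -1), which is
what lets rare or novel populations surface instead of being forced into the
nearest large cluster.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN

from .preprocess import PCEmbedding

logger = logging.getLogger(__name__)

BATCHES = ("reference", "query")


@dataclass
class EmbeddingBundle:
    """Row-aligned per-cell embeddings at three resolutions.

    corrected_pcs: cells x n_pcs batch-corrected PC scores.
    umap2d:        cells x 2 nonlinear embedding.
    cluster:       integer cluster ID per cell; -1 marks DBSCAN noise.
    """

    corrected_pcs: np.ndarray
    umap2d: np.ndarray
    cluster: np.ndarray
    batch: np.ndarray

    def __post_init__(self):
        n = self.corrected_pcs.shape[0]
        if not (self.umap2d.shape[0] == len(self.cluster) == len(self.batch) == n):
            raise ValueError("EmbeddingBundle components are not row-aligned")


def remove_batch_effects(
    pcs: PCEmbedding, batch: np.ndarray, backend: str = "center_fallback"
) -> np.ndarray:
    """Remove reference-vs-query technical offsets in PC space.

    backend="center_fallback": per-batch mean-centering of every PC — removes
    any constant batch offset exactly and keeps the pipeline dependency-light.
    backend="harmony": delegate to the harmonypy implementation of the Harmony
    iterative soft-clustering correction, if installed.
    """
    batch = np.asarray(batch)
    present = set(np.unique(batch))
    if present != set(BATCHES):
        raise ValueError(f"expected batches {BATCHES}, got {sorted(present)}")
    for b in BATCHES:
        if (batch == b).sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 cells")
    x = np.asarray(pcs.scores, dtype=float)
    if backend == "center_fallback":
        out = x.copy()
        for b in BATCHES:
            mask = batch == b
            out[mask] -= out[mask].mean(axis=0, keepdims=True)
        return out
    if backend == "harmony":
        try:
            import harmonypy
        except ImportError as e:  # pragma: no cover
            raise ImportError(
                "backend='harmony' requires the harmonypy package; "
                "use backend='center_fallback' otherwise"
            ) from e
        import pandas as pd

        meta = pd.DataFrame({"batch": batch})
        ho = harmonypy.run_harmony(x, meta, "batch")
        return np.asarray(ho.Z_corr).T
    raise ValueError(f"unknown backend: {backend!r}")


def umap_embed(
    corrected: np.ndarray, n_neighbors: int = 15, min_dist: float = 0.1, seed: int = 0
) -> np.ndarray:
    """2-D UMAP of the corrected PC space; deterministic for a fixed seed.

    Passing a random_state puts umap-learn into its single-threaded exact
    mode, so repeated runs on identical input are bit-reproducible.
    """
    corrected = np.asarray(corrected, dtype=float)
    if n_neighbors >= corrected.shape[0]:
        raise ValueError(
            f"n_neighbors={n_neighbors} must be smaller than the number of cells {corrected.shape[0]}"
        )
    import umap  # deferred: numba jit compilation is slow at import

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning)
        reducer = umap.UMAP(
            n_components=2, n_neighbors=n_neighbors, min_dist=min_dist,
            metric="euclidean", random_state=seed, n_jobs=1,
        )
        return np.asarray(reducer.fit_transform(corrected), dtype=float)


def _renumber(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster IDs 0..m-1 by decreasing size; ties by smallest member index."""
    labels = np.asarray(labels)
    out = np.full(labels.shape, -1, dtype=int)
    ids = [c for c in np.unique(labels) if c != -1]
    keyed = sorted(
        ids, key=lambda c: (-int((labels == c).sum()), int(np.flatnonzero(labels == c)[0]))
    )
    for new, old in enumerate(keyed):
        out[labels == old] = new
    return out


def dbscan_cluster(umap2d: np.ndarray, eps: float = 0.5, min_samples: int = 5) -> np.ndarray:
    """DBSCAN on the 2-D embedding with deterministic cluster renumbering."""
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    if min_samples < 1:
        raise ValueError(f"min_samples must be >= 1, got {min_samples}")
    pts = np.asarray(umap2d, dtype=float)
    if pts.shape[0] == 0:
        return np.empty(0, dtype=int)
    raw = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(pts)
    return _renumber(raw)


def dbscan_bruteforce_oracle(points: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """Naive O(n^2) DBSCAN used only as a test oracle.

    Core point: at least *min_samples* neighbors within *eps*, itself
    included. Clusters are connected components of core points plus their
    border points; everything else is noise (-1). Same renumbering as
    :func:`dbscan_cluster`.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if n > 5000:
        raise ValueError("oracle is quadratic; refusing n > 5000")
    if n == 0:
        return np.empty(0, dtype=int)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    neigh = d2 <= eps ** 2
    core = neigh.sum(axis=1) >= min_samples
    labels = np.full(n, -1, dtype=int)
    cid = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        stack = [i]
        labels[i] = cid
        while stack:
            j = stack.pop()
            for k in np.flatnonzero(neigh[j]):
                if labels[k] == -1:
                    labels[k] = cid
                    if core[k]:
                        stack.append(k)
        cid += 1
    return _renumber(labels)


def build_bundle(
    pcs: PCEmbedding,
    batch: np.ndarray,
    backend: str = "center_fallback",
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    eps: float = 0.5,
    min_samples: int = 5,
    seed: int = 0,
) -> EmbeddingBundle:
    """Run batch correction -> UMAP -> DBSCAN and return the aligned bundle."""
    corrected = remove_batch_effects(pcs, batch, backend=backend)
    coords = umap_embed(corrected, n_neighbors=n_neighbors, min_dist=min_dist, seed=seed)
    cluster = dbscan_cluster(coords, eps=eps, min_samples=min_samples)
    n_clusters = int(cluster.max()) + 1 if (cluster >= 0).any() else 0
    logger.info("embedding: %d cells, %d clusters, %d noise cells",
                len(cluster), n_clusters, int((cluster == -1).sum()))
    return EmbeddingBundle(corrected, coords, cluster, np.asarray(batch))
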