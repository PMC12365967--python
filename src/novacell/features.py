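"""Concatenation of the three embedding resolutions into one feature table.

The classifier sees every cell as a 53-dimensional vector under defaults:
50 batch-corrected PC scores (broad transcriptional programs), 2 UMAP
coordinates (local manifold structure) and 1 integer DBSCAN cluster ID
(an unsupervised grouping, treated as a single categorical feature).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .embed import EmbeddingBundle

CLUSTER_COL = "cluster"


@dataclass
class MultiResolutionFeatures:
    """Cells x (n_pcs + 2 + 1) feature table fed to the classifier."""

    table: pd.DataFrame
    batch: np.ndarray
    resolution_tags: dict[str, str] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.table)

    @property
    def categorical_columns(self) -> list[str]:
        return [c for c, t in self.resolution_tags.items() if t == "cluster"]

    def reference_rows(self) -> pd.DataFrame:
        return self.table.loc[self.batch == "reference"]

    def query_rows(self) -> pd.DataFrame:
        return self.table.loc[self.batch == "query"]


def concatenate_features(bundle: EmbeddingBundle) -> MultiResolutionFeatures:
    """Merge corrected PCs, UMAP coordinates and cluster IDs, row-aligned.

    Columns are ordered [pc_1..pc_n, umap_1, umap_2, cluster]; the numeric
    blocks are carried over unchanged (no rescaling — the tree classifier is
    per-feature scale-invariant) and the cluster ID stays an integer code with
    -1 for noise.
    """
    n = bundle.corrected_pcs.shape[0]
    if not (bundle.umap2d.shape[0] == len(bundle.cluster) == n):
        raise ValueError("bundle components are not row-aligned")
    n_pcs = bundle.corrected_pcs.shape[1]
    cols: dict[str, np.ndarray] = {}
    tags: dict[str, str] = {}
    for i in range(n_pcs):
        name = f"pc_{i + 1}"
        cols[name] = bundle.corrected_pcs[:, i]
        tags[name] = "pc"
    for i in range(2):
        name = f"umap_{i + 1}"
        cols[name] = bundle.umap2d[:, i]
        tags[name] = "umap"
    cols[CLUSTER_COL] = np.asarray(bundle.cluster, dtype=int)
    tags[CLUSTER_COL] = "cluster"
    table = pd.DataFrame(cols)
    return MultiResolutionFeatures(table=table, batch=np.asarray(bundle.batch), resolution_tags=tags)
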