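"""Shared fixtures: the default synthetic benchmark run and small helpers.

The expensive full-pipeline runs (default benchmark, and the same benchmark
with two reference types withheld) are session-scoped so that every test
inspecting them shares one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from novacell.config import RunConfig
from novacell.features import MultiResolutionFeatures
from novacell.pipeline import run_annotation
from novacell.simulate import SIMBENCH_1, SimConfig, holdout_types, simulate_pair


def small_sim_config(seed: int = 7, n_novel: int = 40) -> SimConfig:
    """A reduced reference/query pair that exercises the whole pipeline fast."""
    return SimConfig(
        n_genes=600,
        known_types=[("t1", 80, 80), ("t2", 80, 80), ("t3", 80, 80)],
        novel_types=[("nv", n_novel)] if n_novel else [],
        n_markers=40,
        seed=seed,
    )


def make_features(
    pcs: np.ndarray, umap2d: np.ndarray, cluster: np.ndarray, batch: np.ndarray
) -> MultiResolutionFeatures:
    """Assemble a feature table directly, bypassing the embedding stage."""
    cols = {f"pc_{i + 1}": pcs[:, i] for i in range(pcs.shape[1])}
    tags = {k: "pc" for k in cols}
    cols["umap_1"], cols["umap_2"] = umap2d[:, 0], umap2d[:, 1]
    tags["umap_1"] = tags["umap_2"] = "umap"
    cols["cluster"] = np.asarray(cluster, dtype=int)
    tags["cluster"] = "cluster"
    return MultiResolutionFeatures(
        table=pd.DataFrame(cols), batch=np.asarray(batch), resolution_tags=tags
    )


@pytest.fixture(scope="session")
def simbench():
    return simulate_pair(SIMBENCH_1)


@pytest.fixture(scope="session")
def simbench_run(simbench):
    ref, labels, query, truth = simbench
    out = run_annotation(ref, labels, query, RunConfig())
    return out, labels, truth


@pytest.fixture(scope="session")
def simbench_holdout_run(simbench):
    ref, labels, query, truth = simbench
    drop = sorted(set(labels.labels))[-2:]
    ref2, labels2 = holdout_types(ref, labels, drop)
    out = run_annotation(ref2, labels2, query, RunConfig())
    return out, labels2, truth
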