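"""Synthetic scRNA-seq reference/query pairs with novel query-only cell types.

The generator emulates the structure the annotation problem cares about:
a shared set of cell types measured in two batches, each type carrying a
disjoint block of marker genes with a large fold change, a multiplicative
per-gene technical batch effect on the query side only, variable library
sizes, and negative-binomial counts (mean mu, variance mu + mu^2/theta).
Novel types appear only among query cells — including a rare one of ~20
cells — which is exactly the open-set situation the pipeline must handle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import ExpressionMatrix, LabelTable


@dataclass
class SimConfig:
    """Parameters of one simulated reference/query pair.

    known_types: (name, n_ref_cells, n_query_cells) per shared type.
    novel_types: (name, n_query_cells) per query-only type.
    marker_lfc:  log2 fold change of a type's markers inside that type.
    batch_sd:    SD of the per-gene log-normal batch factor (query side).
    dispersion:  NB inverse-dispersion theta; variance = mu + mu^2/theta.
    libsize_mean/libsize_sd: log-scale parameters of per-cell library factors.
    """

    n_genes: int = 2000
    known_types: list[tuple[str, int, int]] = field(
        default_factory=lambda: [(f"type_{i}", 300, 300) for i in range(1, 6)]
    )
    novel_types: list[tuple[str, int]] = field(
        default_factory=lambda: [("novel_a", 150), ("novel_b", 20)]
    )
    n_markers: int = 50
    marker_lfc: float = 4.0
    batch_sd: float = 0.3
    dispersion: float = 10.0
    libsize_mean: float = 0.0
    libsize_sd: float = 0.3
    seed: int = 20240101

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        from dataclasses import fields as dc_fields

        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        kwargs = dict(data)
        if "known_types" in kwargs:
            kwargs["known_types"] = [tuple(t) for t in kwargs["known_types"]]
        if "novel_types" in kwargs:
            kwargs["novel_types"] = [tuple(t) for t in kwargs["novel_types"]]
        return cls(**kwargs)

    def validate(self) -> None:
        if len(self.known_types) < 2:
            raise ValueError("need at least 2 known types")
        n_types = len(self.known_types) + len(self.novel_types)
        if n_types * self.n_markers > self.n_genes:
            raise ValueError(
                f"{n_types} types x {self.n_markers} markers exceeds {self.n_genes} genes"
            )
        for cnt in ([n for _, n, m in self.known_types for n in (n, m)]
                    + [n for _, n in self.novel_types]):
            if cnt < 0:
                raise ValueError("cell counts must be non-negative")


#: default benchmark fixture used throughout the tests and docs
SIMBENCH_1 = SimConfig()


@dataclass
class SimTruth:
    """Ground truth of a simulated pair: per-cell types and per-gene parameters."""

    cells: pd.DataFrame  # cell_id, true_type, batch
    genes: pd.DataFrame  # gene_id, baseline_mean, marker_of, batch_factor
    config: SimConfig

    def query_truth(self) -> pd.Series:
        q = self.cells[self.cells["batch"] == "query"]
        return pd.Series(q["true_type"].to_numpy(), index=q["cell_id"].to_numpy())


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + mu^2/theta."""
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    out[pos] = rng.negative_binomial(theta, theta / (theta + mu[pos]))
    return out


def simulate_pair(config: SimConfig = SIMBENCH_1) -> tuple[ExpressionMatrix, LabelTable, ExpressionMatrix, SimTruth]:
    """Generate (reference matrix, reference labels, query matrix, truth).

    Gene baseline means are log-normal; each type multiplies its marker block
    by 2**marker_lfc; query cells additionally carry a per-gene log-normal
    batch factor; per-cell library factors are log-normal; counts are NB.
    Deterministic for a fixed config seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    gene_ids = [f"gene_{i:05d}" for i in range(g)]

    baseline = rng.lognormal(mean=-1.0, sigma=1.0, size=g)
    batch_factor = rng.lognormal(mean=0.0, sigma=config.batch_sd, size=g)

    all_types = [name for name, *_ in config.known_types] + [n for n, _ in config.novel_types]
    marker_of = np.array([""] * g, dtype=object)
    marker_idx: dict[str, np.ndarray] = {}
    for t, name in enumerate(all_types):
        idx = np.arange(t * config.n_markers, (t + 1) * config.n_markers)
        marker_idx[name] = idx
        marker_of[idx] = name

    fold = 2.0 ** config.marker_lfc

    def _cells(spec: list[tuple[str, int]], batch: str, prefix: str):
        types = [name for name, n in spec for _ in range(n)]
        n_cells = len(types)
        cell_ids = [f"{prefix}_{i:05d}" for i in range(n_cells)]
        lib = rng.lognormal(config.libsize_mean, config.libsize_sd, size=n_cells)
        mu = np.repeat(baseline[:, None], n_cells, axis=1)
        for name in dict.fromkeys(types):
            cols = np.flatnonzero(np.array(types, dtype=object) == name)
            mu[np.ix_(marker_idx[name], cols)] *= fold
        if batch == "query":
            mu *= batch_factor[:, None]
        mu *= lib[None, :]
        counts = sp.csr_matrix(_nb_draw(rng, mu, config.dispersion))
        return ExpressionMatrix(counts, gene_ids, cell_ids, batch), types

    ref_spec = [(name, n_ref) for name, n_ref, _ in config.known_types]
    query_spec = [(name, n_q) for name, _, n_q in config.known_types] + list(config.novel_types)
    ref, ref_types = _cells(ref_spec, "reference", "ref")
    query, query_types = _cells(query_spec, "query", "qry")

    labels = LabelTable(list(ref.cell_ids), ref_types)
    cells = pd.DataFrame(
        {
            "cell_id": list(ref.cell_ids) + list(query.cell_ids),
            "true_type": ref_types + query_types,
            "batch": ["reference"] * ref.n_cells + ["query"] * query.n_cells,
        }
    )
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "baseline_mean": baseline,
            "marker_of": marker_of,
            "batch_factor": batch_factor,
        }
    )
    return ref, labels, query, SimTruth(cells=cells, genes=genes, config=config)


def holdout_types(
    reference: ExpressionMatrix, labels: LabelTable, types_to_drop: list[str]
) -> tuple[ExpressionMatrix, LabelTable]:
    """Remove all cells of the given types from the reference side only.

    Mirrors the benchmark construction in which one to three cell types are
    withheld from the reference so they become unseen in the query.
    """
    present = set(labels.labels)
    missing = [t for t in types_to_drop if t not in present]
    if missing:
        raise ValueError(f"types not present in reference labels: {missing}")
    if len(present - set(types_to_drop)) < 2:
        raise ValueError("holdout would leave fewer than 2 reference types")
    keep = [c for c, l in zip(labels.cell_ids, labels.labels) if l not in set(types_to_drop)]
    lab = labels.as_series().loc[keep]
    return reference.subset_cells(keep), LabelTable(keep, lab.tolist())
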