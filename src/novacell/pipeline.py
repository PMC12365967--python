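"""End-to-end orchestration: counts in, per-cell annotations out.

Runs the full sequence — gene intersection, normalization, HVG selection,
PCA, batch correction, UMAP, DBSCAN, feature concatenation, classifier
training, confidence thresholding, and label fusion — and returns the final
annotation together with the intermediate artifacts useful for inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import annotate as ann
from . import embed as emb
from . import preprocess as pp
from .config import RunConfig
from .features import MultiResolutionFeatures, concatenate_features
from .io import ExpressionMatrix, LabelTable, align_labels

logger = logging.getLogger(__name__)


@dataclass
class PipelineOutput:
    result: ann.AnnotationResult
    features: MultiResolutionFeatures
    bundle: emb.EmbeddingBundle
    model: ann.ClassifierModel
    hvgs: list[str]
    config: RunConfig


def run_annotation(
    ref: ExpressionMatrix,
    ref_labels: LabelTable,
    query: ExpressionMatrix,
    config: RunConfig | None = None,
) -> PipelineOutput:
    """Annotate every query cell with a known type, a novel ID, or unassigned."""
    config = config or RunConfig()
    ref = ExpressionMatrix(ref.counts, ref.gene_ids, ref.cell_ids, "reference")
    query = ExpressionMatrix(query.counts, query.gene_ids, query.cell_ids, "query")
    ref, ref_labels = align_labels(ref, ref_labels)

    ref_i, query_i = pp.intersect_genes(ref, query, min_genes=config.preprocess.min_shared_genes)
    logger.info("intersected genes: %d shared; reference %d cells, query %d cells",
                ref_i.n_genes, ref_i.n_cells, query_i.n_cells)
    ref_n = pp.normalize(ref_i, scale_factor=config.preprocess.scale_factor)
    query_n = pp.normalize(query_i, scale_factor=config.preprocess.scale_factor)
    combined = pp.combine(ref_i, query_i, ref_n, query_n)
    if ref_n.n_cells != ref_i.n_cells:  # zero-count cells were dropped
        keep = set(ref_n.cell_ids)
        ref_labels = LabelTable(
            [c for c in ref_labels.cell_ids if c in keep],
            [l for c, l in zip(ref_labels.cell_ids, ref_labels.labels) if c in keep],
        )

    n_hvg = min(config.preprocess.n_hvg, len(combined.gene_ids))
    hvgs = pp.select_hvgs(combined, n_hvg=n_hvg)
    pcs = pp.pca_embed(combined, hvgs, n_pcs=config.embed.n_pcs, seed=config.embed.seed)

    bundle = emb.build_bundle(
        pcs,
        combined.batch,
        backend=config.embed.backend,
        n_neighbors=config.embed.umap.n_neighbors,
        min_dist=config.embed.umap.min_dist,
        eps=config.embed.dbscan.eps,
        min_samples=config.embed.dbscan.min_samples,
        seed=config.embed.seed,
    )
    feats = concatenate_features(bundle)

    params = ann.ClassifierParams(
        iterations=config.annotate.iterations,
        depth=config.annotate.depth,
        learning_rate=config.annotate.learning_rate,
        min_gap=config.annotate.min_gap,
        confident_op=config.annotate.confident_op,
    )
    model = ann.train_classifier(feats, ref_labels, params=params, seed=config.annotate.seed)

    _, all_labels, all_pmax = ann.predict_proba(model, feats)
    spec = ann.select_confidence_threshold(all_pmax, K=model.n_classes, min_gap=params.min_gap)
    logger.info("confidence threshold %.4f over K=%d classes (fallback=%s)",
                spec.threshold, spec.K, spec.fallback_used)

    is_query = feats.batch == "query"
    query_cells = [c for c, q in zip(combined.cell_ids, is_query) if q]
    result = ann.resolve_labels(
        query_cells,
        all_labels[is_query],
        all_pmax[is_query],
        spec,
        np.asarray(feats.table["cluster"])[is_query],
        confident_op=params.confident_op,
    )
    return PipelineOutput(result=result, features=feats, bundle=bundle,
                          model=model, hvgs=hvgs, config=config)
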