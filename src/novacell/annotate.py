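"""Supervised classification, confidence thresholding, and label fusion.

A gradient-boosted decision-tree multiclass model (LightGBM) is trained on
the reference cells' multi-resolution features and scored on every cell. The
maximum class probability of a cell measures the model's confidence: values
near 1 mean a clear call, values near 1/K (K = number of reference types)
mean the model is guessing. The confidence cut is placed data-adaptively at
the largest drop in the pooled, descending-sorted max-probabilities of
reference AND query cells. Query cells above the cut keep the classifier
label; cells below it fall back to their density cluster, which becomes a
"novel_<id>" call (or "unassigned" for noise cells).

The single categorical cluster column is handled inside the classifier
wrapper with smoothed target statistics (out-of-fold on the training rows to
avoid target leakage), and the model is prior-anchored: boosting starts from
the cluster-conditional class distribution (init score = log target
statistic) and the trees fit residual corrections on all features, stopped
early on a held-out reference fold so the corrections never erode the
calibration of the probability output. A query-only cluster is a category
never seen during training: its cells receive the prior class frequencies,
and because no reference cell ever carried that category, the residual
corrections do not apply to them — their max-probability therefore sits near
1/K, the low-confidence anchor, which the largest-drop threshold separates
from the confidently classified cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import lightgbm as lgb
import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier

from .features import CLUSTER_COL, MultiResolutionFeatures
from .io import LabelTable

logger = logging.getLogger(__name__)

MIN_CELLS_PER_CLASS = 5


@dataclass
class ClassifierParams:
    iterations: int = 500
    depth: int = 6
    learning_rate: float = 0.1
    min_gap: float = 1e-6
    confident_op: str = "ge"  # cells exactly at threshold count as confident
    ts_smoothing: float = 10.0  # pseudo-count pulling cluster statistics to the prior
    ts_folds: int = 5  # out-of-fold split for leakage-free training statistics
    val_fraction: float = 0.2  # held-out reference share driving early stopping
    early_stopping_rounds: int = 20
    early_stopping_min_delta: float = 1e-3  # smallest per-round log-loss gain that counts


class ClusterTargetEncoder:
    """Smoothed per-class target statistics for the categorical cluster column.

    For cluster c and class k the statistic is
    (n_{c,k} + a * prior_k) / (n_c + a) with pseudo-count a; a category never
    seen during training maps to the prior itself. Training rows are encoded
    out-of-fold so the statistic a row receives never includes its own label.
    """

    def __init__(self, smoothing: float = 10.0, n_folds: int = 5, seed: int = 0):
        self.smoothing = float(smoothing)
        self.n_folds = int(n_folds)
        self.seed = int(seed)
        self.class_names: list[str] = []
        self.prior: np.ndarray | None = None
        self.mapping: dict[int, np.ndarray] = {}

    def _stats(self, codes: np.ndarray, y_idx: np.ndarray) -> dict[int, np.ndarray]:
        k = len(self.class_names)
        out: dict[int, np.ndarray] = {}
        for c in np.unique(codes):
            mask = codes == c
            counts = np.bincount(y_idx[mask], minlength=k).astype(float)
            out[int(c)] = (counts + self.smoothing * self.prior) / (mask.sum() + self.smoothing)
        return out

    def fit_transform(self, codes: np.ndarray, y: pd.Series) -> np.ndarray:
        codes = np.asarray(codes, dtype=int)
        self.class_names = sorted(y.unique())
        lut = {c: i for i, c in enumerate(self.class_names)}
        y_idx = y.map(lut).to_numpy()
        self.prior = np.bincount(y_idx, minlength=len(lut)) / len(y_idx)
        self.mapping = self._stats(codes, y_idx)
        n = len(codes)
        out = np.empty((n, len(lut)))
        folds = np.random.default_rng(self.seed).permutation(n) % max(self.n_folds, 2)
        for f in np.unique(folds):
            hold = folds == f
            stats = self._stats(codes[~hold], y_idx[~hold])
            for i in np.flatnonzero(hold):
                out[i] = stats.get(int(codes[i]), self.prior)
        return out

    def transform(self, codes: np.ndarray) -> np.ndarray:
        codes = np.asarray(codes, dtype=int)
        out = np.empty((len(codes), len(self.class_names)))
        for i, c in enumerate(codes):
            out[i] = self.mapping.get(int(c), self.prior)
        return out

    def columns(self) -> list[str]:
        return [f"cluster_ts_{c}" for c in self.class_names]

    def seen_mask(self, codes: np.ndarray) -> np.ndarray:
        """True for cells whose cluster category occurred among training cells."""
        return np.array([int(c) in self.mapping for c in np.asarray(codes, dtype=int)])


@dataclass
class ClassifierModel:
    """Fitted multiclass model plus the feature schema it was trained on."""

    booster: LGBMClassifier
    class_names: list[str]
    feature_columns: list[str]
    categorical_columns: list[str]
    params: ClassifierParams
    encoder: ClusterTargetEncoder
    cluster_init_gain: float = 0.0  # log-loss reduction of the cluster-statistic init

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass
class ThresholdSpec:
    """The global confidence cut and where the largest probability drop sits."""

    threshold: float
    K: int
    gap_location: tuple[float, float] | None
    fallback_used: bool = False


@dataclass
class AnnotationResult:
    """Final per-query-cell annotation.

    final_label is the reference type name when the classifier is confident,
    "novel_<cluster id>" when it is not and the cell sits in a density
    cluster, and "unassigned" for low-confidence noise cells.
    """

    cell_ids: list[str]
    final_label: np.ndarray
    classifier_label: np.ndarray
    max_probability: np.ndarray
    cluster_id: np.ndarray
    confident: np.ndarray
    threshold: ThresholdSpec

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "final_label": self.final_label,
                "classifier_label": self.classifier_label,
                "max_probability": self.max_probability,
                "cluster_id": self.cluster_id,
                "confident": self.confident,
            }
        )


def train_classifier(
    features: MultiResolutionFeatures,
    labels: LabelTable,
    params: ClassifierParams | None = None,
    seed: int = 0,
) -> ClassifierModel:
    """Fit the prior-anchored multiclass model on the reference feature rows.

    The cluster column is expanded to smoothed per-class target statistics
    (out-of-fold on the training rows); boosting starts from their log as the
    init score and the trees fit residual corrections over all features.
    A stratified held-out reference fold stops the boosting once per-round
    validation log-loss gains fall below a floor, which keeps the probability
    output calibrated instead of letting it saturate. Deterministic for a
    fixed seed (single thread).
    """
    params = params or ClassifierParams()
    ref = features.reference_rows()
    if len(ref) != len(labels):
        raise ValueError(
            f"{len(ref)} reference feature rows but {len(labels)} labels; align inputs first"
        )
    y = pd.Series(labels.labels)
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("need >=2 reference cell types to train a classifier")
    small = counts[counts < MIN_CELLS_PER_CLASS]
    if len(small):
        logger.warning("reference classes with <%d cells: %s",
                       MIN_CELLS_PER_CLASS, dict(small))
    x = ref.reset_index(drop=True)
    encoder = ClusterTargetEncoder(
        smoothing=params.ts_smoothing, n_folds=params.ts_folds, seed=seed
    )
    ts = encoder.fit_transform(x[CLUSTER_COL].to_numpy(), y)
    x_enc = pd.concat(
        [x.drop(columns=[CLUSTER_COL]),
         pd.DataFrame(ts, columns=encoder.columns())], axis=1
    )
    booster = LGBMClassifier(
        objective="multiclass",  # softmax even for K=2, so init scores are per-class
        num_class=len(counts),
        n_estimators=params.iterations,
        max_depth=params.depth,
        num_leaves=2 ** params.depth,
        learning_rate=params.learning_rate,
        random_state=seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbose=-1,
    )
    split = None
    if 0 < params.val_fraction < 1 and counts.min() >= 2:
        from sklearn.model_selection import train_test_split

        try:
            tr, va = train_test_split(
                np.arange(len(y)), test_size=params.val_fraction,
                random_state=seed, stratify=y,
            )
            split = (np.sort(tr), np.sort(va))
        except ValueError:  # stratification impossible (tiny classes)
            split = None
    if split is not None:
        tr, va = split
        booster.fit(
            x_enc.iloc[tr], y.iloc[tr], init_score=np.log(ts[tr]),
            eval_set=[(x_enc.iloc[va], y.iloc[va])], eval_init_score=[np.log(ts[va])],
            callbacks=[lgb.early_stopping(
                params.early_stopping_rounds,
                min_delta=params.early_stopping_min_delta, verbose=False,
            )],
        )
        logger.info("classifier stopped at %d boosting rounds", booster.best_iteration_)
    else:
        booster.fit(x_enc, y, init_score=np.log(ts))
    # log-loss reduction of the cluster-statistic init over the class prior,
    # credited to the cluster feature in importance reports
    class_idx = {c: i for i, c in enumerate(encoder.class_names)}
    y_idx = y.map(class_idx).to_numpy()
    loss_prior = -np.log(encoder.prior[y_idx]).sum()
    loss_ts = -np.log(ts[np.arange(len(y_idx)), y_idx]).sum()
    return ClassifierModel(
        booster=booster,
        class_names=[str(c) for c in booster.classes_],
        feature_columns=list(ref.columns),
        categorical_columns=[CLUSTER_COL],
        params=params,
        encoder=encoder,
        cluster_init_gain=float(max(loss_prior - loss_ts, 0.0)),
    )


def predict_proba(
    model: ClassifierModel, features: MultiResolutionFeatures | pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Class-probability matrix plus argmax label and max probability per cell.

    Cluster IDs never seen during training (query-only clusters) are valid
    input: such cells get the prior class distribution from the target
    statistics, and the boosted corrections — validated only on reference
    clusters — are not applied to them, so their probabilities stay near the
    prior. For cells of reference-supported clusters the prediction is
    softmax(log target statistic + tree correction).
    """
    x = features.table if isinstance(features, MultiResolutionFeatures) else features
    if list(x.columns) != model.feature_columns:
        raise ValueError(
            f"feature schema mismatch: expected {model.feature_columns}, got {list(x.columns)}"
        )
    codes = x[CLUSTER_COL].to_numpy()
    ts = model.encoder.transform(codes)
    x_enc = pd.concat(
        [x.drop(columns=[CLUSTER_COL]).reset_index(drop=True),
         pd.DataFrame(ts, columns=model.encoder.columns())], axis=1
    )
    best_it = getattr(model.booster, "best_iteration_", None)
    correction = model.booster.booster_.predict(
        x_enc, raw_score=True, num_iteration=best_it
    )
    correction = np.atleast_2d(correction)
    if correction.shape[0] != len(x_enc):  # binary case returns one column
        correction = correction.T
    if correction.shape[1] == 1 and model.n_classes == 2:
        correction = np.hstack([-correction, correction])
    seen = model.encoder.seen_mask(codes)
    logits = np.log(ts) + correction * seen[:, None]
    logits -= logits.max(axis=1, keepdims=True)
    proba = np.exp(logits)
    proba = proba / proba.sum(axis=1, keepdims=True)
    arg = proba.argmax(axis=1)
    labels = np.array([model.class_names[i] for i in arg])
    return proba, labels, proba[np.arange(len(arg)), arg]


def select_confidence_threshold(
    pmax_all: np.ndarray, K: int, min_gap: float = 1e-6
) -> ThresholdSpec:
    """Place the confidence cut at the largest drop of the sorted probabilities.

    The pooled max-probabilities (reference and query cells, equal weight) are
    sorted in decreasing order; the threshold is the midpoint of the pair of
    consecutive values with the largest difference (earliest such pair on
    ties), clipped into [1/K, 1). If no consecutive drop exceeds *min_gap*
    the distribution is flat and the anchor 1/K is used instead.
    """
    p = np.asarray(pmax_all, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty probability vector")
    if (p <= 0).any() or (p > 1).any():
        bad = p[(p <= 0) | (p > 1)]
        raise ValueError(f"probabilities outside (0, 1]: {bad[:5]}")
    lo = 1.0 / K
    srt = np.sort(p)[::-1]
    if srt.size == 1:
        return ThresholdSpec(threshold=lo, K=K, gap_location=None, fallback_used=True)
    drops = srt[:-1] - srt[1:]
    i = int(np.argmax(drops))  # argmax returns the first (highest-probability) tie
    if drops[i] < min_gap:
        return ThresholdSpec(threshold=lo, K=K, gap_location=None, fallback_used=True)
    hi, nxt = float(srt[i]), float(srt[i + 1])
    thr = max((hi + nxt) / 2.0, lo)
    return ThresholdSpec(threshold=thr, K=K, gap_location=(hi, nxt), fallback_used=False)


def resolve_labels(
    cell_ids: list[str],
    classifier_labels: np.ndarray,
    pmax: np.ndarray,
    spec: ThresholdSpec,
    cluster: np.ndarray,
    confident_op: str = "ge",
) -> AnnotationResult:
    """Fuse supervised and cluster labels into the final per-cell annotation."""
    classifier_labels = np.asarray(classifier_labels)
    pmax = np.asarray(pmax, dtype=float)
    cluster = np.asarray(cluster, dtype=int)
    if not (len(cell_ids) == len(classifier_labels) == len(pmax) == len(cluster)):
        raise ValueError("inputs are not row-aligned")
    if confident_op == "ge":
        confident = pmax >= spec.threshold
    elif confident_op == "gt":
        confident = pmax > spec.threshold
    else:
        raise ValueError(f"confident_op must be 'ge' or 'gt', got {confident_op!r}")
    final = np.empty(len(cell_ids), dtype=object)
    final[confident] = classifier_labels[confident]
    novel = ~confident & (cluster >= 0)
    final[novel] = [f"novel_{c}" for c in cluster[novel]]
    final[~confident & (cluster < 0)] = "unassigned"
    return AnnotationResult(
        cell_ids=list(cell_ids),
        final_label=final,
        classifier_label=classifier_labels.astype(object),
        max_probability=pmax,
        cluster_id=cluster,
        confident=confident,
        threshold=spec,
    )


def feature_importance(model: ClassifierModel, resolution_tags: dict[str, str]) -> pd.DataFrame:
    """Normalized gain importance per feature, sorted descending.

    Gains of the internal per-class cluster statistics are summed back into
    the single cluster feature. Returns columns (feature, resolution_tag,
    importance, cumulative), with importance summing to 1 so "the top five
    account for X% of the total" can be read off the cumulative column.
    """
    if not hasattr(model.booster, "booster_") or model.booster.booster_ is None:
        raise ValueError("model is not fitted")
    gain = model.booster.booster_.feature_importance(importance_type="gain")
    internal = list(model.booster.booster_.feature_name())
    ts_cols = set(model.encoder.columns())
    agg: dict[str, float] = {"cluster": model.cluster_init_gain}
    for name, g in zip(internal, gain):
        key = "cluster" if name in ts_cols else name
        agg[key] = agg.get(key, 0.0) + float(g)
    features_out = [c for c in model.feature_columns]
    vals = np.array([agg.get(c, 0.0) for c in features_out])
    total = vals.sum()
    share = vals / total if total > 0 else np.full(len(vals), 1.0 / len(vals))
    df = pd.DataFrame(
        {
            "feature": features_out,
            "resolution_tag": [resolution_tags.get(c, "?") for c in features_out],
            "importance": share,
        }
    )
    df = df.sort_values(["importance", "feature"], ascending=[False, True], kind="mergesort")
    df["cumulative"] = df["importance"].cumsum()
    return df.reset_index(drop=True)
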