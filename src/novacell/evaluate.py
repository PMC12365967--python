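"""Evaluation metrics against ground-truth labels.

Three evaluation views are supported: plain per-cell accuracy for closed-set
annotation; a binary "unseen" view in which every cell type absent from the
reference (and every novel/unassigned prediction) collapses to one positive
class, scored with precision/recall/F1; and an aligned confusion matrix in
which predicted novel IDs are matched to the truth types they capture via an
optimal injective assignment, from which per-class recall/precision/F1 of
discovered types are read off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

UNSEEN = "unseen"


@dataclass
class ConfusionMatrix:
    """True-by-predicted count matrix with an injective column alignment.

    ``alignment`` maps predicted label -> true label, chosen to maximize the
    total number of cells on the matched diagonal. In ``counts`` the aligned
    predicted columns are ordered to match their true rows; unmatched
    predicted columns are appended on the right by decreasing size.
    """

    counts: pd.DataFrame  # rows: truth, cols: predicted
    alignment: dict[str, str]

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def overall_accuracy(truth, pred) -> float:
    """Fraction of cells whose predicted label equals the true label."""
    truth, pred = np.asarray(truth), np.asarray(pred)
    if len(truth) != len(pred):
        raise ValueError(f"length mismatch: {len(truth)} vs {len(pred)}")
    if len(truth) == 0:
        raise ValueError("empty label vectors")
    return float((truth == pred).mean())


def map_to_unseen(labels, known: set[str]) -> np.ndarray:
    """Collapse every label outside the reference vocabulary to "unseen".

    Truth types absent from the reference, predicted "novel_<id>" labels and
    "unassigned" all become the single token; known types pass through.
    """
    if not known:
        raise ValueError("known type set is empty")
    return np.array([l if l in known else UNSEEN for l in np.asarray(labels, dtype=object)],
                    dtype=object)


def unseen_f1(truth_mapped, pred_mapped) -> tuple[float, float, float]:
    """Precision, recall, F1 for the binary task of flagging unseen cells."""
    t = np.asarray(truth_mapped) == UNSEEN
    p = np.asarray(pred_mapped) == UNSEEN
    tp = int((t & p).sum())
    fp = int((~t & p).sum())
    fn = int((t & ~p).sum())
    if tp + fp + fn == 0:
        logger.warning("no unseen cells in truth or predictions; returning zeros")
        return 0.0, 0.0, 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1


def aligned_confusion(truth, pred) -> ConfusionMatrix:
    """Confusion matrix with predicted columns aligned to likely true labels.

    The injective predicted->true assignment maximizing total matched cell
    count is found with the Hungarian algorithm on the raw count matrix;
    predicted labels left unmatched (more predictions than truths, or zero
    overlap everywhere) are appended to the right, largest first.
    """
    truth, pred = np.asarray(truth, dtype=object), np.asarray(pred, dtype=object)
    if len(truth) != len(pred) or len(truth) == 0:
        raise ValueError("truth and pred must be nonempty and of equal length")
    raw = pd.crosstab(pd.Series(truth, name="truth"), pd.Series(pred, name="pred"))
    cost = raw.to_numpy()
    rows, cols = linear_sum_assignment(cost, maximize=True)
    alignment: dict[str, str] = {}
    matched_cols: list[str] = []
    order = np.argsort(rows)  # keep true-row order
    for r, c in zip(rows[order], cols[order]):
        if cost[r, c] > 0:
            alignment[raw.columns[c]] = raw.index[r]
            matched_cols.append(raw.columns[c])
    rest = [c for c in raw.columns if c not in matched_cols]
    rest.sort(key=lambda c: (-raw[c].sum(), str(c)))
    # order matched columns by their aligned row's position
    row_pos = {lab: i for i, lab in enumerate(raw.index)}
    matched_cols.sort(key=lambda c: row_pos[alignment[c]])
    return ConfusionMatrix(counts=raw[matched_cols + rest], alignment=alignment)


def per_class_metrics(confusion: ConfusionMatrix, cls: str) -> tuple[float, float, float]:
    """Recall, precision and F1 for one true class via its aligned column.

    Recall is matched cells over the class's row total ("sensitivity" in
    common usage); precision is matched cells over the aligned column total.
    """
    if cls not in confusion.counts.index:
        raise KeyError(f"class {cls!r} not present in confusion matrix rows")
    col = next((p for p, t in confusion.alignment.items() if t == cls), None)
    if col is None:
        raise KeyError(f"no predicted column aligned to class {cls!r}")
    matched = float(confusion.counts.loc[cls, col])
    row_total = float(confusion.counts.loc[cls].sum())
    col_total = float(confusion.counts[col].sum())
    recall = matched / row_total if row_total else 0.0
    precision = matched / col_total if col_total else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return recall, precision, f1


def metrics_report(truth, pred, known: set[str]) -> dict:
    """Bundle the headline metrics into one JSON-serializable dict."""
    tm = map_to_unseen(truth, known)
    pm = map_to_unseen(pred, known)
    prec, rec, f1 = unseen_f1(tm, pm)
    return {
        "overall_accuracy_unseen_collapsed": overall_accuracy(tm, pm),
        "exact_match_accuracy": overall_accuracy(truth, pred),
        "unseen_precision": prec,
        "unseen_recall": rec,
        "unseen_f1": f1,
        "n_cells": int(len(np.asarray(truth))),
    }
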