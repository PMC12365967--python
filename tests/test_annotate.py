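"""Classifier training, confidence thresholding, and label fusion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from novacell import annotate as ann
from novacell.io import LabelTable

from conftest import make_features


def threshold_oracle(pmax, K, min_gap=1e-6):
    """Exhaustive scan over all consecutive sorted pairs (test-side oracle)."""
    srt = sorted(pmax, reverse=True)
    best_i, best_gap = None, -1.0
    for i in range(len(srt) - 1):
        gap = srt[i] - srt[i + 1]
        if gap > best_gap:  # strict: first (highest-probability) tie wins
            best_i, best_gap = i, gap
    if best_i is None or best_gap < min_gap:
        return 1.0 / K, True
    return max((srt[best_i] + srt[best_i + 1]) / 2.0, 1.0 / K), False


class TestSelectConfidenceThreshold:
    def test_worked_example_midpoint(self):
        spec = ann.select_confidence_threshold(
            np.array([0.98, 0.97, 0.95, 0.60, 0.55, 0.50]), K=4
        )
        assert spec.threshold == pytest.approx(0.775)
        assert spec.gap_location == (0.95, 0.60)
        assert not spec.fallback_used

    def test_flat_distribution_falls_back_to_prior(self):
        spec = ann.select_confidence_threshold(np.full(10, 0.5), K=2)
        assert spec.fallback_used
        assert spec.threshold == pytest.approx(0.5)

    def test_single_gap_by_hand(self):
        spec = ann.select_confidence_threshold(np.array([0.9, 0.3]), K=3)
        assert spec.threshold == pytest.approx(0.6)
        assert not spec.fallback_used

    def test_threshold_clipped_to_prior_floor(self):
        spec = ann.select_confidence_threshold(np.array([0.5, 0.1]), K=2)
        assert spec.threshold == pytest.approx(0.5)  # midpoint 0.3 < 1/K

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ann.select_confidence_threshold(np.array([]), K=2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ann.select_confidence_threshold(np.array([0.5, 1.2]), K=2)
        with pytest.raises(ValueError, match="outside"):
            ann.select_confidence_threshold(np.array([0.0, 0.5]), K=2)

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(2, 200))
            p = rng.uniform(1e-9, 1.0, n)
            K = int(rng.integers(2, 10))
            want_t, want_fb = threshold_oracle(p, K)
            spec = ann.select_confidence_threshold(p, K)
            assert spec.threshold == pytest.approx(want_t)
            assert spec.fallback_used == want_fb

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        p=st.lists(st.floats(min_value=1e-6, max_value=1.0, exclude_min=False), min_size=1, max_size=60),
        K=st.integers(min_value=2, max_value=8),
    )
    def test_threshold_in_valid_range(self, p, K):
        spec = ann.select_confidence_threshold(np.array(p), K=K)
        assert 1.0 / K <= spec.threshold < 1.0


def _blob_features(n_per=100, seed=0, informative_cluster=True, query_blobs=0):
    """Two well-separated reference classes, optionally plus query-only blobs."""
    rng = np.random.default_rng(seed)
    blocks, clusters, batches, labels = [], [], [], []
    for k in range(2):
        b = rng.standard_normal((n_per, 5))
        b[:, 0] += 12.0 * k
        blocks.append(b)
        clusters += [k if informative_cluster else 0] * n_per
        batches += ["reference"] * n_per
        labels += [f"class_{k}"] * n_per
    for q in range(query_blobs):
        b = rng.standard_normal((n_per, 5))
        b[:, 1] += 15.0 * (q + 1)
        blocks.append(b)
        clusters += [2 + q] * n_per
        batches += ["query"] * n_per
    pcs = np.vstack(blocks)
    umap2d = pcs[:, :2].copy()
    feats = make_features(pcs, umap2d, np.array(clusters), np.array(batches))
    lab = LabelTable([f"r{i}" for i in range(2 * n_per)], labels)
    return feats, lab


class TestTrainAndPredict:
    def test_separable_classes_high_training_accuracy(self):
        feats, lab = _blob_features(informative_cluster=False)
        model = ann.train_classifier(feats, lab, seed=0)
        _, pred, _ = ann.predict_proba(model, feats.reference_rows())
        acc = (pred == np.array(lab.labels)).mean()
        assert acc >= 0.99

    def test_probabilities_sum_to_one(self):
        feats, lab = _blob_features(query_blobs=1)
        model = ann.train_classifier(feats, lab, seed=0)
        proba, _, pmax = ann.predict_proba(model, feats)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert (pmax >= 1.0 / model.n_classes - 1e-9).all()

    def test_single_class_rejected(self):
        feats, lab = _blob_features()
        lab = LabelTable(lab.cell_ids, ["only"] * len(lab))
        with pytest.raises(ValueError, match="2 reference cell types"):
            ann.train_classifier(feats, lab)

    def test_unseen_cluster_id_gets_prior_probabilities(self):
        feats, lab = _blob_features(query_blobs=1)
        model = ann.train_classifier(feats, lab, seed=0)
        proba, _, pmax = ann.predict_proba(model, feats)
        is_query = feats.batch == "query"
        np.testing.assert_allclose(proba[is_query], 0.5, atol=1e-9)

    def test_schema_mismatch_rejected(self):
        feats, lab = _blob_features()
        model = ann.train_classifier(feats, lab, seed=0)
        bad = feats.table.rename(columns={"pc_1": "oops"})
        with pytest.raises(ValueError, match="schema"):
            ann.predict_proba(model, bad)

    def test_deterministic_given_seed(self):
        feats, lab = _blob_features(query_blobs=1)
        m1 = ann.train_classifier(feats, lab, seed=11)
        m2 = ann.train_classifier(feats, lab, seed=11)
        p1, _, _ = ann.predict_proba(m1, feats)
        p2, _, _ = ann.predict_proba(m2, feats)
        np.testing.assert_array_equal(p1, p2)


class TestResolveLabels:
    @pytest.mark.parametrize(
        "pmax,cluster,expected,confident",
        [
            (0.9, 6, "beta", True),
            (0.5, 6, "novel_6", False),
            (0.5, -1, "unassigned", False),
        ],
    )
    def test_per_cell_rule(self, pmax, cluster, expected, confident):
        spec = ann.ThresholdSpec(threshold=0.775, K=4, gap_location=(0.95, 0.6))
        res = ann.resolve_labels(
            ["q0"], np.array(["beta"]), np.array([pmax]), spec, np.array([cluster])
        )
        assert res.final_label[0] == expected
        assert bool(res.confident[0]) == confident

    def test_exact_threshold_counts_as_confident(self):
        spec = ann.ThresholdSpec(threshold=0.775, K=4, gap_location=None)
        res = ann.resolve_labels(
            ["q0"], np.array(["beta"]), np.array([0.775]), spec, np.array([2])
        )
        assert res.final_label[0] == "beta"

    def test_raising_threshold_is_monotone(self):
        rng = np.random.default_rng(0)
        n = 200
        labels = np.array(["a"] * n)
        pmax = rng.uniform(0.2, 1.0, n)
        cluster = rng.integers(-1, 4, n)
        spec_lo = ann.ThresholdSpec(threshold=0.4, K=2, gap_location=None)
        spec_hi = ann.ThresholdSpec(threshold=0.7, K=2, gap_location=None)
        lo = ann.resolve_labels([f"q{i}" for i in range(n)], labels, pmax, spec_lo, cluster)
        hi = ann.resolve_labels([f"q{i}" for i in range(n)], labels, pmax, spec_hi, cluster)
        assert not (hi.confident & ~lo.confident).any()

    def test_labels_partition_all_cells(self):
        rng = np.random.default_rng(1)
        n = 300
        pmax = rng.uniform(0.2, 1.0, n)
        cluster = rng.integers(-1, 5, n)
        spec = ann.ThresholdSpec(threshold=0.6, K=3, gap_location=None)
        res = ann.resolve_labels(
            [f"q{i}" for i in range(n)], np.array(["t"] * n), pmax, spec, cluster
        )
        known = res.confident
        novel = np.array([str(l).startswith("novel_") for l in res.final_label])
        unassigned = res.final_label == "unassigned"
        assert ((known.astype(int) + novel.astype(int) + unassigned.astype(int)) == 1).all()


class TestFeatureImportance:
    def test_importances_normalized_and_cumulative(self):
        feats, lab = _blob_features()
        model = ann.train_classifier(feats, lab, seed=0)
        imp = ann.feature_importance(model, feats.resolution_tags)
        assert imp["importance"].sum() == pytest.approx(1.0, abs=1e-6)
        top1 = imp["importance"].iloc[0]
        top5 = imp["cumulative"].iloc[4]
        assert top1 <= top5 <= 1.0 + 1e-9

    def test_cluster_ranks_first_when_it_determines_labels(self):
        # labels are a pure function of the cluster ID; numerics are noise
        rng = np.random.default_rng(2)
        n = 300
        pcs = rng.standard_normal((n, 5))
        cluster = rng.integers(0, 3, n)
        labels = [f"class_{c}" for c in cluster]
        feats = make_features(pcs, rng.standard_normal((n, 2)), cluster,
                              np.array(["reference"] * n))
        lab = LabelTable([f"r{i}" for i in range(n)], labels)
        model = ann.train_classifier(feats, lab, seed=0)
        imp = ann.feature_importance(model, feats.resolution_tags)
        assert imp["feature"].iloc[0] == "cluster"

    def test_unfitted_model_rejected(self):
        feats, lab = _blob_features()
        model = ann.train_classifier(feats, lab, seed=0)
        model.booster = ann.LGBMClassifier()
        with pytest.raises(ValueError, match="fitted"):
            ann.feature_importance(model, feats.resolution_tags)
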