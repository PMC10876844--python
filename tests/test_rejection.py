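"""Rejection contracts: thresholding, metrics oracle, sweep properties."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bayeshead as bh
from bayeshead.bayesify import MCPrediction
from bayeshead.errors import EmptySubsetError
from bayeshead.rejection import compute_metrics


def make_pred(p1: float, uncertainty: float) -> MCPrediction:
    mean = np.array([1 - p1, p1])
    return MCPrediction(
        mean_probs=mean,
        std_probs=np.array([uncertainty, uncertainty]),
        predicted_class=int(mean.argmax()),
        uncertainty=uncertainty,
        n_samples=100,
    )


class TestApplyThreshold:
    def test_hand_example(self):
        res = bh.apply_threshold([0.001, 0.05, 0.003], 0.002)
        assert list(res.accepted) == [True, False, False]
        assert res.fraction_retained == pytest.approx(1 / 3)

    def test_threshold_above_max_accepts_all(self):
        res = bh.apply_threshold([0.01, 0.2, 0.15], 0.2)
        assert res.accepted.all() and res.fraction_retained == 1.0

    def test_zero_threshold_rejects_all_positive(self):
        res = bh.apply_threshold([0.01, 0.2], 0.0)
        assert not res.accepted.any() and res.fraction_retained == 0.0

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            bh.apply_threshold([0.1], -0.1)

    @given(
        u=st.lists(st.floats(0, 1), min_size=1, max_size=20),
        t1=st.floats(0, 1),
        t2=st.floats(0, 1),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_accepted_sets_nested_in_threshold(self, u, t1, t2):
        lo, hi = sorted((t1, t2))
        a_lo = bh.apply_threshold(u, lo).accepted
        a_hi = bh.apply_threshold(u, hi).accepted
        assert np.all(a_hi[a_lo])  # accepted(lo) subset of accepted(hi)


class TestComputeMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics([1, 0, 1, 0], [0.9, 0.1, 0.8, 0.2], [1, 0, 1, 0])
        assert m.accuracy == 1.0 and m.f1 == 1.0

    def test_hand_counted_confusion(self):
        m = compute_metrics([1, 1, 0, 1], [0.9, 0.8, 0.3, 0.6], [1, 1, 0, 0])
        assert m.accuracy == pytest.approx(0.75)
        assert m.precision == pytest.approx(2 / 3)
        assert m.recall == pytest.approx(1.0)
        assert m.f1 == pytest.approx(0.8)

    def test_auc_on_ordered_and_reversed_scores(self):
        truth = [1, 1, 0, 0]
        assert compute_metrics([1, 1, 0, 0], [0.9, 0.8, 0.3, 0.2], truth).auc == 1.0
        assert compute_metrics([1, 1, 0, 0], [0.2, 0.3, 0.8, 0.9], truth).auc == 0.0

    def test_exhaustive_confusion_matrix_oracle(self):
        """All 2^4 predicted patterns against a fixed truth vs direct counting."""
        truth = np.array([1, 1, 0, 0])
        scores = np.array([0.9, 0.8, 0.3, 0.2])
        for pattern in product([0, 1], repeat=4):
            pred = np.array(pattern)
            tp = int(np.sum((pred == 1) & (truth == 1)))
            fp = int(np.sum((pred == 1) & (truth == 0)))
            fn = int(np.sum((pred == 0) & (truth == 1)))
            tn = int(np.sum((pred == 0) & (truth == 0)))
            m = compute_metrics(pred, scores, truth)
            assert m.accuracy == pytest.approx((tp + tn) / 4)
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            assert m.precision == pytest.approx(prec)
            assert m.recall == pytest.approx(rec)
            assert m.f1 == pytest.approx(f1)

    def test_single_class_truth_flags_auc_undefined(self):
        m = compute_metrics([1, 1], [0.9, 0.8], [1, 1])
        assert m.auc is None and m.accuracy == 1.0

    def test_empty_subset_raises_distinct_error(self):
        with pytest.raises(EmptySubsetError):
            compute_metrics([], [], [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([1], [0.5, 0.4], [1, 0])


class TestThresholdCurve:
    def test_full_retention_row_equals_baseline(self):
        preds = [make_pred(p, u) for p, u in
                 [(0.9, 0.001), (0.2, 0.003), (0.8, 0.04), (0.4, 0.08)]]
        truth = [1, 0, 1, 1]
        tc = bh.threshold_curve(preds, truth, thresholds=(0.01, 0.1, 0.15))
        base = compute_metrics(
            [p.predicted_class for p in preds], [p.mean_probs[1] for p in preds], truth
        )
        for t in (0.1, 0.15):
            row = tc.row(t)
            assert row["fraction"] == 1.0
            assert row["accuracy"] == base.accuracy
            assert row["auc"] == base.auc

    def test_fraction_monotone_on_default_grid(self):
        rng = np.random.default_rng(0)
        preds = [make_pred(rng.uniform(), rng.uniform(0, 0.25)) for _ in range(30)]
        truth = rng.integers(0, 2, 30)
        tc = bh.threshold_curve(preds, truth)
        frac = tc.frame["fraction"].to_numpy()
        assert np.all(np.diff(frac) >= 0)
        assert np.all(np.diff(tc.frame["threshold"].to_numpy()) > 0)

    def test_hand_built_six_sample_sweep(self):
        """3 certain-correct, 2 uncertain-wrong, 1 uncertain-correct."""
        preds = [
            make_pred(0.9, 0.001), make_pred(0.1, 0.001), make_pred(0.95, 0.001),
            make_pred(0.8, 0.05), make_pred(0.3, 0.05),  # wrong, uncertain
            make_pred(0.85, 0.05),  # correct, uncertain
        ]
        truth = [1, 0, 1, 0, 1, 1]
        tc = bh.threshold_curve(preds, truth, thresholds=(0.01, 0.1))
        assert tc.row(0.01)["accuracy"] == 1.0
        assert tc.row(0.01)["fraction"] == pytest.approx(0.5)
        assert tc.row(0.1)["accuracy"] == pytest.approx(4 / 6)

    def test_empty_subset_rows_flagged_not_fatal(self):
        preds = [make_pred(0.9, 0.5)]
        tc = bh.threshold_curve(preds, [1], thresholds=(0.001, 1.0))
        assert np.isnan(tc.row(0.001)["accuracy"])
        assert tc.row(0.001)["fraction"] == 0.0
        assert tc.row(1.0)["accuracy"] == 1.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            bh.threshold_curve([make_pred(0.9, 0.1)], [1], thresholds=())
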