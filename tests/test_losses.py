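"""Weighted cross-entropy, generalized dice and their sum."""

import numpy as np
import pytest

from voxhazard.autodiff import Tensor
from voxhazard.losses import (LossWeights, combined_loss, generalized_dice_loss,
                              weighted_cross_entropy)


def _logits_for(probabilities):
    """Scores whose softmax reproduces the given probabilities."""
    return np.log(np.asarray(probabilities, dtype=float))


def _brute_force_generalized_dice(probs, labels, eps):
    """Direct scalar evaluation of the squared-reciprocal-volume dice.

    probs: (C, ...) normalized class probabilities; labels: integer field.
    Independent of the package implementation: plain Python loops over
    classes and voxels.
    """
    C = probs.shape[0]
    y = [(labels == c).astype(float) for c in range(C)]
    vols = [float(yc.sum()) for yc in y]
    finite = [1.0 / v**2 for v in vols if v > 0]
    top = max(finite) if finite else 0.0
    w = [1.0 / v**2 if v > 0 else top for v in vols]
    numer = 2 * sum(w[c] * float((y[c] * probs[c]).sum()) for c in range(C)) + eps
    denom = sum(
        w[c] * float(probs[c].sum() + y[c].sum()) for c in range(C)
    ) + eps
    return 1.0 - numer / denom


class TestWeightedCrossEntropy:
    def test_uniform_prediction_is_ln2(self):
        scores = _logits_for([[0.5, 0.5]])
        for label in (0, 1):
            loss = weighted_cross_entropy(scores, [label], LossWeights())
            assert float(loss.data) == pytest.approx(np.log(2), rel=1e-9)

    def test_certain_correct_prediction_is_zero(self):
        scores = np.array([[50.0, -50.0]])
        loss = weighted_cross_entropy(scores, [0], LossWeights())
        assert float(loss.data) == pytest.approx(0.0, abs=1e-12)

    def test_quarter_probability_batch_is_ln4(self):
        scores = _logits_for([[0.25, 0.75], [0.75, 0.25]])
        loss = weighted_cross_entropy(scores, [0, 1], LossWeights())
        assert float(loss.data) == pytest.approx(np.log(4), rel=1e-9)

    def test_weighted_mean_reduction_formula(self):
        # hand evaluation: loss = (w0*(-ln .25) + w1*(-ln .5)) / (w0 + w1)
        scores = _logits_for([[0.25, 0.75], [0.5, 0.5]])
        w = LossWeights(ce_class_weights=(2.0, 0.5))
        loss = weighted_cross_entropy(scores, [0, 1], w)
        expect = (2.0 * np.log(4) + 0.5 * np.log(2)) / 2.5
        assert float(loss.data) == pytest.approx(expect, rel=1e-9)

    def test_weight_rescaling_invariance(self, rng):
        scores = rng.standard_normal((6, 2))
        labels = rng.integers(0, 2, 6)
        a = weighted_cross_entropy(scores, labels, LossWeights((0.7, 1.3)))
        b = weighted_cross_entropy(scores, labels, LossWeights((7.0, 13.0)))
        assert float(a.data) == pytest.approx(float(b.data), rel=1e-9)

    def test_nonnegative_and_gradient_direction(self, rng):
        scores = Tensor(rng.standard_normal((4, 2)), requires_grad=True)
        labels = np.array([0, 1, 0, 1])
        loss = weighted_cross_entropy(scores, labels, LossWeights())
        assert float(loss.data) >= 0
        loss.backward()
        # gradient pushes the true-class score up (negative gradient entry)
        for i, lab in enumerate(labels):
            assert scores.grad[i, lab] < 0


class TestGeneralizedDice:
    def test_perfect_prediction_loss_vanishes(self, rng):
        labels = rng.integers(0, 3, (1, 4, 4, 4))
        scores = np.stack([40.0 * (labels == c) for c in range(3)], axis=1)
        loss = generalized_dice_loss(scores, labels, epsilon=1e-5)
        assert float(loss.data) <= 1e-6

    def test_total_mismatch_loss_near_one(self):
        labels = np.zeros((1, 2, 2, 2), dtype=int)
        wrong = np.full((1, 2, 2, 2), 2)
        scores = np.stack([40.0 * (wrong == c) for c in range(3)], axis=1)
        loss = generalized_dice_loss(scores, labels, epsilon=1e-5)
        assert float(loss.data) >= 0.999

    def test_matches_brute_force_on_soft_predictions(self, rng):
        for _ in range(10):
            labels = rng.integers(0, 3, (2, 2, 2, 2))
            scores = rng.standard_normal((2, 3, 2, 2, 2))
            e = np.exp(scores - scores.max(axis=1, keepdims=True))
            probs = e / e.sum(axis=1, keepdims=True)
            expect = np.mean([
                _brute_force_generalized_dice(probs[n], labels[n], 1e-5)
                for n in range(2)
            ])
            loss = generalized_dice_loss(scores, labels, epsilon=1e-5)
            assert float(loss.data) == pytest.approx(expect, rel=1e-9)

    def test_eight_voxel_frozen_value(self):
        # hand-checkable 8-voxel instance: one class-1 voxel, one class-2,
        # six background; uniform predicted probabilities (1/3 everywhere)
        labels = np.zeros((1, 2, 2, 2), dtype=int)
        labels[0, 0, 0, 0] = 1
        labels[0, 1, 1, 1] = 2
        scores = np.zeros((1, 3, 2, 2, 2))
        # w = (1/36, 1, 1); intersections w*y*yhat = (6/3)/36, 1/3, 1/3
        # denom = w*(sum yhat + sum y) = (8/3+6)/36 + (8/3+1) + (8/3+1)
        eps = 1e-5
        expect = 1 - (2 * (2.0 / 36 + 1 / 3 + 1 / 3) + eps) / (
            (8 / 3 + 6) / 36 + 2 * (8 / 3 + 1) + eps
        )
        loss = generalized_dice_loss(scores, labels, epsilon=eps)
        assert float(loss.data) == pytest.approx(expect, rel=1e-9)
        assert float(loss.data) == pytest.approx(0.80929, abs=1e-5)

    def test_absent_class_no_nan(self):
        labels = np.zeros((1, 3, 3, 3), dtype=int)  # classes 1, 2 empty
        scores = np.random.default_rng(0).standard_normal((1, 3, 3, 3, 3))
        loss = generalized_dice_loss(scores, labels, epsilon=1e-5)
        assert np.isfinite(loss.data)
        assert 0 <= float(loss.data) <= 1 + 1e-6

    def test_voxel_permutation_invariance(self, rng):
        labels = rng.integers(0, 3, (1, 2, 2, 2))
        scores = rng.standard_normal((1, 3, 2, 2, 2))
        base = float(generalized_dice_loss(scores, labels, 1e-5).data)
        perm = rng.permutation(8)
        lab_p = labels.reshape(1, -1)[:, perm].reshape(1, 2, 2, 2)
        sc_p = scores.reshape(1, 3, -1)[:, :, perm].reshape(1, 3, 2, 2, 2)
        assert float(generalized_dice_loss(sc_p, lab_p, 1e-5).data) == \
            pytest.approx(base, rel=1e-12)

    def test_blending_toward_truth_never_increases(self, rng):
        # convex interpolation from a random prediction to the exact one-hot
        for _ in range(50):
            labels = rng.integers(0, 3, (1, 4, 4, 4))
            onehot = np.stack([(labels == c).astype(float) for c in range(3)],
                              axis=1)
            e = np.exp(rng.standard_normal((1, 3, 4, 4, 4)))
            probs = e / e.sum(axis=1, keepdims=True)
            losses = []
            for t in np.linspace(0, 1, 6):
                blend = (1 - t) * probs + t * onehot
                losses.append(_brute_force_generalized_dice(
                    blend[0], labels[0], 1e-5))
            assert all(a >= b - 1e-12 for a, b in zip(losses, losses[1:]))


class TestCombinedLoss:
    def test_sum_of_components(self, rng):
        class_scores = rng.standard_normal((3, 2))
        labels = rng.integers(0, 2, 3)
        seg_scores = rng.standard_normal((3, 3, 2, 2, 2))
        masks = rng.integers(0, 3, (3, 2, 2, 2))
        w = LossWeights(ce_class_weights=(0.65127, 1.34672))
        total = combined_loss(class_scores, labels, seg_scores, masks, w)
        parts = float(weighted_cross_entropy(class_scores, labels, w).data) + \
            float(generalized_dice_loss(seg_scores, masks, w.epsilon).data)
        assert float(total.data) == pytest.approx(parts, rel=1e-12)

    def test_known_component_values_add(self):
        class_scores = _logits_for([[0.5, 0.5]])
        labels = [0]
        seg_labels = np.random.default_rng(3).integers(0, 3, (1, 2, 2, 2))
        seg_scores = np.stack(
            [40.0 * (seg_labels == c) for c in range(3)], axis=1)
        total = combined_loss(class_scores, labels, seg_scores, seg_labels,
                              LossWeights())
        assert float(total.data) == pytest.approx(np.log(2), abs=1e-5)

    def test_validation_errors(self, rng):
        with pytest.raises(ValueError):
            weighted_cross_entropy(rng.standard_normal((2, 2)), [0, 2],
                                   LossWeights())
        with pytest.raises(ValueError):
            generalized_dice_loss(rng.standard_normal((1, 3, 2, 2, 2)),
                                  rng.integers(0, 3, (1, 3, 3, 3)))
        with pytest.raises(ValueError):
            LossWeights(ce_class_weights=(0.0, 1.0))
        with pytest.raises(ValueError):
            LossWeights(epsilon=0.0)
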