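"""Hand-checked values and invariants of the imbalance-aware objective."""

from __future__ import annotations

import math

import numpy as np
import pytest

from neuroseg3d import nn
from neuroseg3d.losses import LossConfig, combined_loss, dice_loss, weighted_ce
from neuroseg3d.volume import one_hot


def scalar_loss_oracle(probs, labels, cfg: LossConfig):
    """Independent pure-Python evaluation of both loss components."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels).ravel()
    flat = probs.reshape(-1, cfg.num_classes)
    # weighted CE: mean over voxels of -w_c log p_c
    wce = 0.0
    for p, c in zip(flat, labels):
        wce += -cfg.class_weights[c] * math.log(max(p[c], 1e-12))
    wce /= len(labels)
    # soft dice with Laplace smoothing
    total = 0.0
    for c in range(cfg.num_classes):
        inter = sq_p = sq_g = 0.0
        for p, lbl in zip(flat, labels):
            g = 1.0 if lbl == c else 0.0
            inter += p[c] * g
            sq_p += p[c] ** 2
            sq_g += g ** 2
        total += (2 * inter + cfg.epsilon) / (sq_p + sq_g + cfg.epsilon)
    dice = 1.0 - total / cfg.num_classes
    return wce, dice


def _single_voxel(p_true: float, cls: int):
    probs = np.full((1, 1, 1, 4), (1.0 - p_true) / 3.0)
    probs[..., cls] = p_true
    target = np.full((1, 1, 1), cls, dtype=np.int64)
    return probs, target


class TestWeightedCE:
    def test_perfect_prediction_approaches_zero(self):
        probs, target = _single_voxel(1.0 - 1e-9, 2)
        assert weighted_ce(probs, target).item() < 1e-6

    def test_trigeminal_voxel_at_half_confidence(self):
        # w_TN * (-ln 0.5) = 300 * 0.693147... ~ 207.944
        probs, target = _single_voxel(0.5, 3)
        val = weighted_ce(probs, target).item()
        assert val == pytest.approx(300.0 * math.log(2.0), rel=1e-6)
        assert val == pytest.approx(207.944, abs=1e-3)

    def test_background_to_trigeminal_weight_ratio_is_300(self):
        p3, t3 = _single_voxel(0.5, 3)
        p0, t0 = _single_voxel(0.5, 0)
        l3 = weighted_ce(p3, t3).item()
        l0 = weighted_ce(p0, t0).item()
        assert l0 == pytest.approx(math.log(2.0), rel=1e-6)
        assert l3 / l0 == pytest.approx(300.0, rel=1e-6)

    def test_unnormalized_probabilities_rejected(self):
        probs = np.full((2, 2, 2, 4), 0.5)
        with pytest.raises(ValueError, match="normalized"):
            weighted_ce(probs, np.zeros((2, 2, 2), dtype=int))


class TestDiceLoss:
    def test_perfect_one_hot_prediction_is_exactly_zero(self):
        rng = np.random.default_rng(0)
        target = rng.integers(0, 4, size=(4, 5, 5))
        probs = one_hot(target).astype(np.float64)
        assert dice_loss(probs, target).item() == pytest.approx(0.0, abs=1e-12)

    def test_fully_wrong_class_term_is_smoothing_over_2n(self):
        # pred puts class 3 on 10 voxels disjoint from the 10 true ones:
        # that class contributes eps / (2n + eps) = 1/21
        target = np.zeros((1, 20, 1), dtype=np.int64)
        target[0, :10, 0] = 3
        pred_lab = np.zeros_like(target)
        pred_lab[0, 10:, 0] = 3
        probs = one_hot(pred_lab).astype(np.float64)
        cfg = LossConfig()
        loss = dice_loss(probs, target, cfg).item()
        _, dice_o = scalar_loss_oracle(probs, target, cfg)
        assert loss == pytest.approx(dice_o, abs=1e-9)
        # class 3 and class 0 are each fully disjoint with n = 10 on both
        # sides: term = eps/(2n+eps) = 1/21; classes 1, 2 are absent
        # everywhere -> eps/eps = 1
        term_disjoint = 1.0 / 21.0
        expected = 1.0 - (term_disjoint + 1.0 + 1.0 + term_disjoint) / 4.0
        assert loss == pytest.approx(expected, abs=1e-9)

    def test_uniform_probabilities_match_scalar_oracle(self):
        probs = np.full((1, 1, 1, 4), 0.25)
        target = np.array([[[2]]], dtype=np.int64)
        cfg = LossConfig()
        _, dice_o = scalar_loss_oracle(probs, target, cfg)
        assert dice_loss(probs, target, cfg).item() == pytest.approx(dice_o, abs=1e-6)

    def test_matches_oracle_on_random_soft_predictions(self):
        rng = np.random.default_rng(1)
        logits = rng.standard_normal((3, 4, 2, 4))
        probs = np.exp(logits) / np.exp(logits).sum(-1, keepdims=True)
        target = rng.integers(0, 4, size=(3, 4, 2))
        cfg = LossConfig()
        wce_o, dice_o = scalar_loss_oracle(probs, target, cfg)
        assert dice_loss(probs, target, cfg).item() == pytest.approx(dice_o, rel=1e-9)
        assert weighted_ce(probs, target, cfg).item() == pytest.approx(wce_o, rel=1e-9)

    def test_literal_squared_variant_not_zero_at_perfect_soft_prediction(self):
        target = np.zeros((2, 2, 2), dtype=np.int64)
        probs = np.clip(one_hot(target).astype(np.float64), 0.02, 0.94)
        probs /= probs.sum(-1, keepdims=True)
        std = dice_loss(probs, target, LossConfig()).item()
        lit = dice_loss(probs, target, LossConfig(squared_numerator=True)).item()
        assert lit > std


class TestCombinedLoss:
    def _toy(self):
        rng = np.random.default_rng(2)
        logits = nn.Tensor(rng.standard_normal((1, 2, 2, 2, 4)), requires_grad=True)
        target = rng.integers(0, 4, size=(1, 2, 2, 2))
        return logits, target

    def test_alpha_half_averages_the_components(self):
        logits, target = self._toy()
        probs = nn.softmax(logits, axis=-1)
        cfg = LossConfig(alpha=0.5)
        combo = combined_loss(None, logits, target, cfg).item()
        expected = 0.5 * (weighted_ce(probs, target, cfg).item()
                          + dice_loss(probs, target, cfg).item())
        assert combo == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("alpha,which", [(1.0, "wce"), (0.0, "dice")])
    def test_alpha_extremes_select_one_component(self, alpha, which):
        logits, target = self._toy()
        probs = nn.softmax(logits, axis=-1)
        cfg = LossConfig(alpha=alpha)
        combo = combined_loss(None, logits, target, cfg).item()
        ref = (weighted_ce if which == "wce" else dice_loss)(probs, target, cfg).item()
        assert combo == pytest.approx(ref, rel=1e-9)

    def test_alpha_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            LossConfig(alpha=1.5)

    def test_monotone_in_true_class_probability(self):
        # raising p_true at one voxel never increases either loss
        cfg = LossConfig()
        target = np.zeros((1, 1, 1), dtype=np.int64)
        target[0, 0, 0] = 3
        prev_wce = prev_dice = np.inf
        for p in np.linspace(0.1, 0.95, 10):
            probs, _ = np.full((1, 1, 1, 4), (1 - p) / 3.0), None
            probs[..., 3] = p
            w = weighted_ce(probs, target, cfg).item()
            d = dice_loss(probs, target, cfg).item()
            assert w <= prev_wce + 1e-12 and d <= prev_dice + 1e-12
            prev_wce, prev_dice = w, d

    def test_gradient_imbalance_ratio_matches_class_weights(self):
        # equal per-voxel errors: the trigeminal class drives a 300x larger
        # CE gradient on its probability than background does
        cfg = LossConfig()

        def grad_for(cls):
            probs = nn.Tensor(np.full((1, 1, 1, 4), 0.25), requires_grad=True)
            target = np.full((1, 1, 1), cls, dtype=np.int64)
            weighted_ce(probs, target, cfg).backward()
            return abs(probs.grad[0, 0, 0, cls])

        assert grad_for(3) / grad_for(0) == pytest.approx(300.0, rel=1e-9)
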