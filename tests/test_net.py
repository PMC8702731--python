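"""Architecture contracts of the two-stage cascade."""

from __future__ import annotations

import numpy as np
import pytest

import neuroseg3d as ns
from neuroseg3d import nn
from neuroseg3d.losses import combined_loss
from neuroseg3d.net import (
    CSAM3D, CoarseNet, NetConfig, RefineStage, Res2Block3D, build_model,
)
from neuroseg3d.nn import Tensor

TINY = dict(base_width=8, depth=2, refiner_width=8, refiner_depth=1)


def _rand_input(shape=(1, 8, 16, 16, 1), seed=0):
    return Tensor(np.random.default_rng(seed).standard_normal(shape).astype(np.float32))


class TestRes2Block:
    def test_spatial_shape_preserved_and_subset_split(self):
        rng = np.random.default_rng(0)
        block = Res2Block3D(8, 32, rng, s=4)
        assert block.sub == 8  # 32 internal channels -> four 8-channel subsets
        x = _rand_input((1, 4, 8, 8, 8))
        out = block(x)
        assert out.shape == (1, 4, 8, 8, 32)

    def test_first_subset_passes_through_unchanged(self):
        # zero every 3x3x3 subset conv: subset 1 of the pre-fusion features
        # must equal subset 1 of the post-input-conv features regardless
        rng = np.random.default_rng(1)
        block = Res2Block3D(4, 8, rng, s=4)
        for conv in block.convs:
            conv.weight.data[:] = 0.0
        x = _rand_input((1, 4, 4, 4, 4), seed=1)
        t = nn.relu(block.in_bn(block.in_conv(x)))
        ys = block.hierarchical_subsets(t)
        assert np.array_equal(ys[0].data, t.data[..., : block.sub])

    def test_indivisible_channels_rejected_at_build(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="divisible"):
            Res2Block3D(4, 10, rng, s=4)


class TestCoarseStage:
    def test_confidence_map_shape_and_normalization(self):
        model = build_model(NetConfig(**TINY, refine=False))
        img = np.random.default_rng(0).random((8, 32, 32)).astype(np.float32)
        logits, cmap = model.coarse_forward(img)
        assert logits.shape == (1, 8, 32, 32, 4)
        assert cmap.probabilities.shape == (4, 8, 32, 32)
        assert np.allclose(cmap.probabilities.sum(axis=0), 1.0, atol=1e-5)

    def test_zeroed_head_gives_uniform_quarter(self):
        model = build_model(NetConfig(**TINY, refine=False))
        model.coarse.head.weight.data[:] = 0.0
        model.coarse.head.bias.data[:] = 0.0
        img = np.random.default_rng(0).random((8, 16, 16)).astype(np.float32)
        _, cmap = model.coarse_forward(img)
        assert np.allclose(cmap.probabilities, 0.25, atol=1e-6)

    def test_indivisible_spatial_dims_rejected(self):
        model = build_model(NetConfig(**TINY, refine=False))
        img = np.zeros((6, 16, 16), dtype=np.float32)  # 6 not divisible by 4
        with pytest.raises(ValueError, match="divisible"):
            model.coarse_forward(img)


class TestRefineStage:
    def test_five_channel_input_four_channel_output(self):
        rng = np.random.default_rng(0)
        stage = RefineStage(NetConfig(**TINY), rng)
        img = _rand_input((1, 4, 8, 8, 1))
        p = nn.softmax(_rand_input((1, 4, 8, 8, 4), seed=2), axis=-1)
        f = nn.concat([img, p], axis=-1)
        assert f.shape[-1] == 5
        out = stage(img, p)
        assert out.shape == (1, 4, 8, 8, 4)

    def test_zeroed_refiner_degenerates_to_linear_recalibration(self):
        # with every U-Net parameter zeroed, the residual sum leaves P and
        # the output pre-softmax is exactly the 1x1x1 projection of P
        rng = np.random.default_rng(3)
        stage = RefineStage(NetConfig(**TINY), rng)
        for p in stage.unet.parameters():
            p.data[:] = 0.0
        stage.eval()
        img = _rand_input((1, 4, 8, 8, 1))
        p = nn.softmax(_rand_input((1, 4, 8, 8, 4), seed=4), axis=-1)
        out = stage(img, p)
        expected = nn.conv3d(p, stage.project.weight, stage.project.bias)
        assert np.allclose(out.data, expected.data, atol=1e-6)

    def test_misaligned_shapes_rejected(self):
        rng = np.random.default_rng(0)
        stage = RefineStage(NetConfig(**TINY), rng)
        with pytest.raises(ValueError, match="differ"):
            stage(_rand_input((1, 4, 8, 8, 1)), _rand_input((1, 4, 4, 4, 4)))


class TestCascade:
    def test_refine_flag_controls_second_stage(self):
        full = build_model(NetConfig(**TINY, refine=True))
        coarse_only = build_model(NetConfig(**TINY, refine=False))
        x = _rand_input((1, 8, 16, 16, 1))
        c1, r1 = full(x)
        c2, r2 = coarse_only(x)
        assert r1 is not None and r2 is None
        assert full.num_parameters() > coarse_only.num_parameters()

    def test_resblock_arm_builds_and_runs(self):
        model = build_model(NetConfig(**TINY, block="resblock", refine=False))
        c, r = model(_rand_input((1, 8, 16, 16, 1)))
        assert c.shape[-1] == 4 and r is None

    def test_attention_identity_at_initialisation(self):
        # the attention scalars start at zero, so CSAM is an identity map
        rng = np.random.default_rng(5)
        csam = CSAM3D(8, rng)
        x = _rand_input((1, 2, 4, 4, 8), seed=6)
        assert np.allclose(csam(x).data, x.data)

    def test_flip_equivariance_with_symmetric_kernels(self):
        # convolution commutes with a spatial flip only when the kernel is
        # flip-symmetric; symmetrize every conv kernel, disable attention,
        # then the whole cascade must commute with an axis flip
        model = build_model(NetConfig(**TINY, attention=False, seed=7))
        for mod in model.modules():
            if isinstance(mod, nn.Conv3d) and mod.kernel == 3:
                w = mod.weight.data
                w_sym = np.zeros_like(w)
                for fz in (1, -1):
                    for fh in (1, -1):
                        for fw in (1, -1):
                            w_sym += w[::fz, ::fh, ::fw]
                mod.weight.data = (w_sym / 8.0).astype(w.dtype)
        model.eval()
        img = np.random.default_rng(8).random((8, 16, 16)).astype(np.float32)
        for axis in range(3):
            flipped = np.flip(img, axis=axis).copy()
            c1, r1 = model(Tensor(img[None, ..., None]))
            c2, r2 = model(Tensor(flipped[None, ..., None]))
            assert np.allclose(np.flip(r1.data, axis=axis + 1), r2.data, atol=1e-4)

    def test_end_to_end_gradients_match_finite_differences(self):
        """Analytic gradients of the full training loss on a width-4 cascade
        agree with central differences to 1e-3."""
        cfg = NetConfig(base_width=4, depth=1, refiner_width=4, refiner_depth=1,
                        s=4, seed=9)
        model = build_model(cfg).to_dtype(np.float64)
        rng = np.random.default_rng(9)
        img = rng.random((1, 2, 4, 4, 1))
        target = rng.integers(0, 4, size=(1, 2, 4, 4))

        def loss_value():
            c, r = model(Tensor(img))
            return combined_loss(c, r, target).item()

        c, r = model(Tensor(img, requires_grad=False))
        loss = combined_loss(c, r, target)
        loss.backward()
        eps = 1e-6
        checked = 0
        for name, p in model.named_parameters()[::3]:
            flat = p.data.ravel()
            gflat = p.grad.ravel()
            for idx in range(0, flat.size, max(1, flat.size // 3)):
                old = flat[idx]
                flat[idx] = old + eps
                fp = loss_value()
                flat[idx] = old - eps
                fm = loss_value()
                flat[idx] = old
                num = (fp - fm) / (2 * eps)
                assert num == pytest.approx(gflat[idx], rel=1e-3, abs=1e-6), name
                checked += 1
        assert checked >= 20
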