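"""Two-stage coarse-to-fine 3D segmentation network.

Stage 1 (coarse) is an encoder--decoder for tubular structures with
multi-scale residual blocks (Res2 blocks: the channels are split into ``s``
subsets processed by a hierarchy of 3x3x3 convolutions, which widens the
receptive-field mix inside a single block) and an optional channel/spatial
self-attention module at the bottleneck. Its softmaxed output is a 4-class
confidence map P.

Stage 2 (refine) concatenates the raw volume I with P into a 5-channel
input F = cat(I, P), runs a plain 3D U-Net over F, sums the U-Net's 4-channel
output features with P, and projects with a 1x1x1 convolution back to 4
classes. Both stages are differentiable end to end.

Activations are channels-last ``(N, Z, H, W, C)``; the public entry points
accept plain (Z, H, W) arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .volume import NUM_CLASSES

__all__ = [
    "NetConfig", "ConfidenceMap", "ResBlock3D", "Res2Block3D", "CSAM3D",
    "UNet3D", "CoarseNet", "RefineStage", "CascadeNet", "build_model",
]


@dataclass
class NetConfig:
    """Architecture knobs; defaults give the full proposed model.

    ``block`` selects the coarse-stage feature extractor ('resblock' or
    'res2block'); ``refine``/``attention`` switch the refinement stage and the
    bottleneck attention for ablations.
    """

    in_channels: int = 1
    num_classes: int = NUM_CLASSES
    base_width: int = 16
    depth: int = 3                       # pooling levels in the coarse stage
    s: int = 4                           # Res2 subset count
    block: str = "res2block"             # {"resblock", "res2block"}
    attention: bool = True
    refine: bool = True
    refiner_width: int = 32              # flat width of the U-Net refiner
    refiner_depth: int = 2
    sum_probabilities: bool = True       # sum softmaxed P (vs raw logits) in refine
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block not in ("resblock", "res2block"):
            raise ValueError(f"unknown block type {self.block!r}")
        if self.base_width <= 0 or self.refiner_width <= 0:
            raise ValueError("widths must be positive")
        if self.s < 2:
            raise ValueError("Res2 subset count s must be >= 2")


@dataclass
class ConfidenceMap:
    """Per-class probability field P with shape (4, Z, H, W).

    Channel sums are 1 per voxel (softmax output).
    """

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities)
        if p.ndim != 4 or p.shape[0] != NUM_CLASSES:
            raise ValueError(f"expected (4, Z, H, W), got {p.shape}")
        sums = p.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-5):
            raise ValueError("confidence map channels must sum to 1 per voxel")
        if p.min() < -1e-7 or p.max() > 1.0 + 1e-7:
            raise ValueError("confidence map entries must lie in [0, 1]")
        self.probabilities = p

    def argmax_labels(self) -> np.ndarray:
        return np.argmax(self.probabilities, axis=0).astype(np.int16)


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class ResBlock3D(nn.Module):
    """Plain residual block: two 3x3x3 conv-BN(-ReLU) plus identity/projection."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv3d(cin, cout, 3, rng, bias=False)
        self.bn1 = nn.BatchNorm3d(cout)
        self.conv2 = nn.Conv3d(cout, cout, 3, rng, bias=False)
        self.bn2 = nn.BatchNorm3d(cout)
        self.proj = nn.Conv3d(cin, cout, 1, rng, bias=False) if cin != cout else None

    def forward(self, x: Tensor) -> Tensor:
        y = nn.relu(self.bn1(self.conv1(x)))
        y = self.bn2(self.conv2(y))
        skip = self.proj(x) if self.proj is not None else x
        return nn.relu(y + skip)


class Res2Block3D(nn.Module):
    """Multi-scale residual block with hierarchical subset convolutions.

    After a leading 1x1x1 convolution (channel count kept at ``cout``), the
    features are split equally into ``s`` subsets x_i. Subset 1 passes
    through unchanged; each later subset goes through conv-BN-ReLU, with
    subsets i > 2 first summed with the previous subset's output:

        y_1 = x_1
        y_2 = relu(BN(K(x_2)))
        y_i = relu(BN(K(x_i + y_{i-1}))),  2 < i <= s.

    The y_i are concatenated and fused by a trailing 1x1x1 convolution; a
    residual skip wraps the whole block.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, s: int = 4):
        super().__init__()
        if cout % s != 0:
            raise ValueError(
                f"Res2Block internal channels ({cout}) must be divisible by s={s}"
            )
        self.s = s
        self.sub = cout // s
        self.in_conv = nn.Conv3d(cin, cout, 1, rng, bias=False)
        self.in_bn = nn.BatchNorm3d(cout)
        self.convs = [nn.Conv3d(self.sub, self.sub, 3, rng, bias=False) for _ in range(s - 1)]
        self.bns = [nn.BatchNorm3d(self.sub) for _ in range(s - 1)]
        self.fuse = nn.Conv3d(cout, cout, 1, rng, bias=False)
        self.fuse_bn = nn.BatchNorm3d(cout)
        self.proj = nn.Conv3d(cin, cout, 1, rng, bias=False) if cin != cout else None

    def hierarchical_subsets(self, t: Tensor) -> list[Tensor]:
        """Split ``t`` (already through the leading 1x1x1 conv) and apply the
        hierarchical subset transforms; returns [y_1 .. y_s] pre-fusion."""
        xs = [nn.narrow(t, -1, i * self.sub, self.sub) for i in range(self.s)]
        ys = [xs[0]]
        for i in range(1, self.s):
            inp = xs[i] if i == 1 else xs[i] + ys[i - 1]
            ys.append(nn.relu(self.bns[i - 1](self.convs[i - 1](inp))))
        return ys

    def forward(self, x: Tensor) -> Tensor:
        t = nn.relu(self.in_bn(self.in_conv(x)))
        ys = self.hierarchical_subsets(t)
        fused = self.fuse_bn(self.fuse(nn.concat(ys, axis=-1)))
        skip = self.proj(x) if self.proj is not None else x
        return nn.relu(fused + skip)


class CSAM3D(nn.Module):
    """Channel and spatial self-attention at the bottleneck.

    Spatial branch: 1x1x1 query/key projections to C/8 channels, value at C;
    an (M x M) affinity over the M bottleneck voxels reweights the values.
    Channel branch: a (C x C) affinity from the Gram matrix of the flattened
    features reweights channels. Each branch is scaled by a learnable scalar
    initialised to zero, so the module is an identity at initialisation; the
    two deltas are added to the input.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        inner = max(1, channels // 8)
        self.query = nn.Conv3d(channels, inner, 1, rng, bias=False)
        self.key = nn.Conv3d(channels, inner, 1, rng, bias=False)
        self.value = nn.Conv3d(channels, channels, 1, rng, bias=False)
        self.gamma_spatial = nn.Parameter(np.zeros(1))
        self.gamma_channel = nn.Parameter(np.zeros(1))

    def forward(self, x: Tensor) -> Tensor:
        n, z, h, w, c = x.shape
        m = z * h * w
        flat = nn.reshape(x, (n, m, c))
        # spatial affinity
        q = nn.reshape(self.query(x), (n, m, -1))
        k = nn.reshape(self.key(x), (n, m, -1))
        v = nn.reshape(self.value(x), (n, m, c))
        att = nn.softmax(nn.matmul(q, nn.transpose(k, (0, 2, 1))), axis=-1)
        spatial = nn.matmul(att, v)
        # channel affinity (Gram matrix of the flattened features)
        energy = nn.matmul(nn.transpose(flat, (0, 2, 1)), flat)
        catt = nn.softmax(energy, axis=-1)
        channel = nn.matmul(flat, nn.transpose(catt, (0, 2, 1)))
        delta = self.gamma_spatial * nn.reshape(spatial, x.shape) \
            + self.gamma_channel * nn.reshape(channel, x.shape)
        return x + delta


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _make_block(kind: str, cin: int, cout: int, rng, s: int) -> nn.Module:
    if kind == "res2block":
        return Res2Block3D(cin, cout, rng, s=s)
    return ResBlock3D(cin, cout, rng)


class CoarseNet(nn.Module):
    """Encoder--decoder coarse stage producing 4-class logits."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        w = cfg.base_width
        widths = [w * 2 ** i for i in range(cfg.depth)]
        self.enc = []
        cin = cfg.in_channels
        for cout in widths:
            self.enc.append(_make_block(cfg.block, cin, cout, rng, cfg.s))
            cin = cout
        bw = w * 2 ** cfg.depth
        self.bottleneck = _make_block(cfg.block, cin, bw, rng, cfg.s)
        self.csam = CSAM3D(bw, rng) if cfg.attention else None
        self.dec = []
        cin = bw
        for cout in reversed(widths):
            self.dec.append(_make_block(cfg.block, cin + cout, cout, rng, cfg.s))
            cin = cout
        self.pool = nn.MaxPool3d()
        self.up = nn.UpsampleNearest3d()
        self.head = nn.Conv3d(widths[0], cfg.num_classes, 1, rng)

    def _check_dims(self, shape) -> None:
        div = 2 ** self.cfg.depth
        bad = [d for d in shape if d % div]
        if bad:
            raise ValueError(
                f"coarse stage with depth {self.cfg.depth} needs spatial dims "
                f"divisible by {div}; got {tuple(shape)}"
            )

    def forward(self, x: Tensor) -> Tensor:
        self._check_dims(x.shape[1:4])
        skips = []
        for block in self.enc:
            x = block(x)
            skips.append(x)
            x = self.pool(x)
        x = self.bottleneck(x)
        if self.csam is not None:
            x = self.csam(x)
        for block, skip in zip(self.dec, reversed(skips)):
            x = self.up(x)
            x = block(nn.concat([x, skip], axis=-1))
        return self.head(x)


class UNet3D(nn.Module):
    """Plain 3D U-Net with a flat per-layer channel width."""

    def __init__(self, in_channels: int, out_channels: int, width: int,
                 depth: int, rng: np.random.Generator):
        super().__init__()
        self.depth = depth
        self.enc = []
        cin = in_channels
        for _ in range(depth):
            self.enc.append(nn.Sequential(
                nn.conv_bn_relu(cin, width, 3, rng),
                nn.conv_bn_relu(width, width, 3, rng),
            ))
            cin = width
        self.mid = nn.Sequential(
            nn.conv_bn_relu(cin, width, 3, rng),
            nn.conv_bn_relu(width, width, 3, rng),
        )
        self.dec = []
        for _ in range(depth):
            self.dec.append(nn.Sequential(
                nn.conv_bn_relu(2 * width, width, 3, rng),
                nn.conv_bn_relu(width, width, 3, rng),
            ))
        self.pool = nn.MaxPool3d()
        self.up = nn.UpsampleNearest3d()
        self.head = nn.Conv3d(width, out_channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        skips = []
        for block in self.enc:
            x = block(x)
            skips.append(x)
            x = self.pool(x)
        x = self.mid(x)
        for block, skip in zip(self.dec, reversed(skips)):
            x = self.up(x)
            x = block(nn.concat([x, skip], axis=-1))
        return self.head(x)


class RefineStage(nn.Module):
    """Refiner: U-Net over F = cat(I, P), residual sum with P, 1x1x1 projection."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        super().__init__()
        self.unet = UNet3D(cfg.in_channels + cfg.num_classes, cfg.num_classes,
                           cfg.refiner_width, cfg.refiner_depth, rng)
        self.project = nn.Conv3d(cfg.num_classes, cfg.num_classes, 1, rng)

    def forward(self, img: Tensor, p: Tensor) -> Tensor:
        if img.shape[:4] != p.shape[:4]:
            raise ValueError(f"image/confidence-map shapes differ: {img.shape} vs {p.shape}")
        f = nn.concat([img, p], axis=-1)  # 5 channels
        feats = self.unet(f)
        return self.project(feats + p)


class CascadeNet(nn.Module):
    """The full two-stage model; ``refine`` can be disabled for ablations."""

    def __init__(self, cfg: NetConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.coarse = CoarseNet(cfg, rng)
        self.refiner = RefineStage(cfg, rng) if cfg.refine else None

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor | None]:
        coarse_logits = self.coarse(x)
        if self.refiner is None:
            return coarse_logits, None
        p = nn.softmax(coarse_logits, axis=-1) if self.cfg.sum_probabilities else coarse_logits
        refined_logits = self.refiner(x, p)
        return coarse_logits, refined_logits

    # -- ndarray-facing helpers --------------------------------------------
    @staticmethod
    def _to_tensor(img_values: np.ndarray) -> Tensor:
        arr = np.asarray(img_values, dtype=np.float32)
        if arr.ndim != 3:
            raise ValueError(f"expected a (Z, H, W) volume, got {arr.shape}")
        return Tensor(arr[None, ..., None])

    def coarse_forward(self, img_values: np.ndarray) -> tuple[Tensor, ConfidenceMap]:
        """Run the coarse stage on one (Z, H, W) volume."""
        logits = self.coarse(self._to_tensor(img_values))
        probs = nn.softmax(logits, axis=-1)
        return logits, ConfidenceMap(np.moveaxis(probs.data[0], -1, 0))

    def predict_labels(self, img_values: np.ndarray) -> np.ndarray:
        """Argmax prediction for one normalized (Z, H, W) volume (eval mode)."""
        was_training = self.training
        self.eval()
        try:
            coarse_logits, refined = self.forward(self._to_tensor(img_values))
            logits = refined if refined is not None else coarse_logits
            return np.argmax(logits.data[0], axis=-1).astype(np.int16)
        finally:
            self.train(was_training)


def build_model(cfg: NetConfig | None = None, **overrides) -> CascadeNet:
    if cfg is None:
        cfg = NetConfig(**overrides)
    elif overrides:
        cfg = NetConfig(**{**cfg.__dict__, **overrides})
    return CascadeNet(cfg)
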