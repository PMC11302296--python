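"""The modified 3D-UNet: voxelwise 3-class segmentation plus 2-class molecule
classification driven by the masked density product.

Architecture, in order:

1. A 3D U-Net over the input density grid: ``depth`` encoder levels with
   channel counts ``feature_size * 2**level``, two same-padded convolutions
   (edge ``filter_size``) with rectifier nonlinearities per level, 2× max
   pooling between levels, and a mirrored decoder with nearest-neighbor
   upsampling and skip concatenation, ending in a 1×1×1 head that emits
   3 segmentation score channels (medium / low / high reactivity).
2. The modification block: a 1×1×1 convolution collapses the 3 segmentation
   channels to one; that map multiplies the input density elementwise
   (the "masked density"); batch normalization; adaptive max pooling to
   ``pooled_size``³; and two fully connected layers
   pooled_size³ → final_layer_neurons → 2 producing the hazard-class scores.

The block is assembled from a declared stage order so the alternative
arrangement (pooling before normalization) is a one-line configuration
change. Segmentation scores enter the 1×1 convolution raw (no softmax);
set ``normalize_seg_scores`` to route them through a softmax first.

Ties in both argmaxes resolve to the lowest class index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import BatchNorm3d, Conv3d, Linear, Module

__all__ = ["NetworkConfig", "HazardNet", "build_network", "forward", "predict"]

SEG_CLASSES = 3  # low/medium/high reactivity — fixed by the task
OUT_CLASSES = 2  # allowed vs prohibited — fixed by the task

_DEFAULT_ORDER = ("conv", "multiply", "batchnorm", "pool")


@dataclass(frozen=True)
class NetworkConfig:
    in_shape: Tuple[int, int, int] = (32, 32, 32)
    feature_size: int = 28
    filter_size: int = 4
    depth: int = 3
    final_layer_neurons: int = 16
    pooled_size: int = 4
    mask_channels: int = 1  # channels kept by the 1x1 collapse (1, 2 or 3)
    two_channel_input: bool = False  # feed the electronegativity map as a 2nd channel
    normalize_seg_scores: bool = False
    modification_order: Tuple[str, ...] = _DEFAULT_ORDER

    def __post_init__(self):
        if self.feature_size < 1 or self.filter_size < 2 or self.depth < 1:
            raise ValueError("feature_size >= 1, filter_size >= 2, depth >= 1 required")
        div = 2 ** (self.depth - 1)
        if any(n % div for n in self.in_shape):
            raise ValueError(
                f"in_shape {self.in_shape} must be divisible by 2**(depth-1) = {div}"
            )
        if sorted(self.modification_order) != sorted(_DEFAULT_ORDER):
            raise ValueError(f"modification_order must be a permutation of {_DEFAULT_ORDER}")
        if self.modification_order.index("conv") > self.modification_order.index("multiply"):
            raise ValueError("the 1x1 convolution must precede the multiplication")
        if not 1 <= self.mask_channels <= SEG_CLASSES:
            raise ValueError("mask_channels must be between 1 and 3")

    @property
    def in_channels(self) -> int:
        return 2 if self.two_channel_input else 1


class _ConvBlock(Module):
    """Two same-padded convolutions, each followed by a rectifier."""

    def __init__(self, cin: int, cout: int, k: int, rng):
        super().__init__()
        self.conv1 = Conv3d(cin, cout, k, rng)
        self.conv2 = Conv3d(cout, cout, k, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv2(self.conv1(x).relu()).relu()


class HazardNet(Module):
    """U-Net segmentation backbone plus the masking/classification block."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        f, k, depth = config.feature_size, config.filter_size, config.depth

        chans = [f * 2**l for l in range(depth)]
        self.enc_blocks = _ModuleList(
            _ConvBlock(config.in_channels if l == 0 else chans[l - 1], chans[l], k, rng)
            for l in range(depth)
        )
        self.up_convs = _ModuleList(
            Conv3d(chans[l + 1], chans[l], k, rng) for l in range(depth - 1)
        )
        self.dec_blocks = _ModuleList(
            _ConvBlock(2 * chans[l], chans[l], k, rng) for l in range(depth - 1)
        )
        self.seg_head = Conv3d(chans[0], SEG_CLASSES, 1, rng)
        # bias the segmentation head at the log prior of the percentile
        # masks (80/10/10): training starts from a background-dominant
        # prediction instead of drifting into minority-flooding, which the
        # volume-reweighted dice loss otherwise barely penalizes
        self.seg_head.bias.data = np.log(
            np.array([0.8, 0.1, 0.1], dtype=np.float32))
        mc = config.mask_channels
        self.mask_conv = Conv3d(SEG_CLASSES, mc, 1, rng)
        # start the 1x1 collapse at reactive-region indicators (ignore the
        # background channel): the product with the density then realizes
        # the "masked density" semantics from step one and training refines
        # the mix. One kept channel sums the low/high classes; two keep
        # them separate; three add the background.
        seeds = {1: [[0, 1, 1]], 2: [[0, 1, 0], [0, 0, 1]],
                 3: [[1, 0, 0], [0, 1, 0], [0, 0, 1]]}[mc]
        self.mask_conv.weight.data = (
            np.array(seeds, dtype=np.float32).reshape(mc, 3, 1, 1, 1)
            + self.mask_conv.weight.data * 0.1
        )
        self.bn = BatchNorm3d(mc)
        p3 = config.pooled_size**3 * mc
        self.fc1 = Linear(p3, config.final_layer_neurons, rng)
        self.fc2 = Linear(config.final_layer_neurons, OUT_CLASSES, rng)
        self._last_masked: np.ndarray | None = None

    # -- pieces -----------------------------------------------------------
    def _unet(self, x: Tensor) -> Tensor:
        skips = []
        h = x
        for l, block in enumerate(self.enc_blocks):
            h = block(h)
            if l < len(self.enc_blocks) - 1:
                skips.append(h)
                h = ad.max_pool2x(h)
        for l in reversed(range(len(self.dec_blocks))):
            h = self.up_convs[l](ad.upsample2x(h)).relu()
            h = self.dec_blocks[l](ad.concat([skips[l], h], axis=1))
        return self.seg_head(h)

    def _modification_block(self, seg_scores: Tensor, density: Tensor) -> Tensor:
        seg_in = seg_scores
        if self.config.normalize_seg_scores:
            seg_in = ad.log_softmax(seg_in, axis=1).exp()
        h = None
        for stage in self.config.modification_order:
            if stage == "conv":
                h = self.mask_conv(seg_in)
            elif stage == "multiply":
                h = h * density
                self._last_masked = h.data
            elif stage == "batchnorm":
                h = self.bn(h)
            elif stage == "pool":
                h = ad.adaptive_max_pool(h, self.config.pooled_size)
        n = h.data.shape[0]
        h = h.reshape(n, -1)
        return self.fc2(self.fc1(h).relu())

    # -- API --------------------------------------------------------------
    def forward(self, batch: np.ndarray | Tensor) -> tuple[Tensor, Tensor]:
        """batch: (N, C, D, H, W) or (N, D, H, W) densities → (seg, class) scores."""
        x = batch if isinstance(batch, Tensor) else Tensor(np.asarray(batch, dtype=np.float32))
        if x.ndim == 4:
            x = x.reshape(x.shape[0], 1, *x.shape[1:])
        if x.data.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} input channel(s), got {x.data.shape[1]}"
            )
        if tuple(x.data.shape[2:]) != tuple(self.config.in_shape):
            raise ValueError(
                f"batch spatial shape {x.data.shape[2:]} != configured {self.config.in_shape}"
            )
        if not np.all(np.isfinite(x.data)):
            raise ValueError("input batch contains non-finite values")
        seg_scores = self._unet(x)
        # the product always masks the *density* channel (channel 0)
        density = Tensor(x.data[:, :1], _prev=(x,))
        if x.requires_grad:
            def _bw(g, _x=x):
                full = np.zeros_like(_x.data)
                full[:, :1] = g
                _x._accum(full)
            density._backward = _bw
        class_scores = self._modification_block(seg_scores, density)
        return seg_scores, class_scores


class _ModuleList(Module):
    def __init__(self, modules):
        super().__init__()
        self._list = list(modules)
        for i, m in enumerate(self._list):
            self._modules[str(i)] = m

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


def build_network(config: NetworkConfig, seed: int = 0) -> HazardNet:
    """Construct the network with deterministic parameter initialization."""
    return HazardNet(config, seed=seed)


def forward(network: HazardNet, density_batch) -> tuple[Tensor, Tensor]:
    return network(density_batch)


def predict(network: HazardNet, density_batch) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel mask argmax and per-sample label argmax (lowest index wins ties)."""
    was_training = network.training
    network.eval()
    try:
        with ad.no_grad():
            seg_scores, class_scores = network(density_batch)
    finally:
        network.train(was_training)
    mask_pred = seg_scores.data.argmax(axis=1).astype(np.int8)
    label_pred = class_scores.data.argmax(axis=1)
    return mask_pred, label_pred
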