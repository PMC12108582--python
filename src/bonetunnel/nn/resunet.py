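"""Residual-encoder U-net for per-slice bone-tunnel segmentation.

The encoder follows the ResNet50 layout: a 7x7 stride-2 stem convolution
plus 3x3 stride-2 max pooling, then four stages of 1x1/3x3/1x1 bottleneck
blocks repeated (3, 4, 6, 3) times, with stride-2 spatial reduction in the
last three stages. Every convolution is followed by batch normalization and
ReLU. Five down-sampling steps take an H x W input to ceil(H/32) (a
600 x 600 slice reaches a 19 x 19 x 2048 bottleneck); a symmetric decoder
with skip connections up-samples back to the input size and a final 1x1
convolution emits two per-pixel class scores (background / tunnel).

A reduced-width variant (``ModelSpec.small()``: base width 8, one block per
stage) preserves the stride/shape contract for fast CPU experiments.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import (
    Adam,
    BatchNorm2d,
    Conv2d,
    Layer,
    MaxPool2d,
    Param,
    ReLU,
    ResizeNearest,
    softmax_channels,
)

MIN_INPUT_SIDE = 32

#: ResNet50 stage repeats.
RESNET50_REPEATS = (3, 4, 6, 3)


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters.

    ``base_width`` is the stem channel count (64 for the full ResNet50,
    whose bottleneck then reaches ``32 * base_width`` = 2048 channels);
    ``encoder_repeats`` are the per-stage bottleneck repeat counts.
    """

    num_classes: int = 2
    in_channels: int = 3
    base_width: int = 64
    encoder_repeats: tuple[int, int, int, int] = RESNET50_REPEATS
    seed: int = 0

    @classmethod
    def small(cls, seed: int = 0) -> "ModelSpec":
        """Reduced-width desk-scale variant (same stride arithmetic)."""
        return cls(base_width=8, encoder_repeats=(1, 1, 1, 1), seed=seed)

    @property
    def bottleneck_channels(self) -> int:
        return 32 * self.base_width


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def set_train(self, mode):
        self.train_mode = mode
        for l in self.layers:
            l.set_train(mode)

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


def _conv_bn_relu(in_ch, out_ch, kernel, stride, rng) -> Sequential:
    return Sequential(
        Conv2d(in_ch, out_ch, kernel, stride, rng=rng),
        BatchNorm2d(out_ch),
        ReLU(),
    )


class Bottleneck(Layer):
    """1x1 -> 3x3 (stride) -> 1x1 residual block with projection shortcut."""

    def __init__(self, in_ch: int, width: int, out_ch: int, stride: int, rng):
        self.path = Sequential(
            Conv2d(in_ch, width, 1, 1, rng=rng), BatchNorm2d(width), ReLU(),
            Conv2d(width, width, 3, stride, rng=rng), BatchNorm2d(width), ReLU(),
            Conv2d(width, out_ch, 1, 1, rng=rng), BatchNorm2d(out_ch),
        )
        self.shortcut = None
        if stride != 1 or in_ch != out_ch:
            self.shortcut = Sequential(
                Conv2d(in_ch, out_ch, 1, stride, rng=rng), BatchNorm2d(out_ch))
        self.relu = ReLU()

    def parameters(self):
        ps = self.path.parameters()
        if self.shortcut is not None:
            ps += self.shortcut.parameters()
        return ps

    def set_train(self, mode):
        self.train_mode = mode
        self.path.set_train(mode)
        if self.shortcut is not None:
            self.shortcut.set_train(mode)
        self.relu.set_train(mode)

    def forward(self, x):
        y = self.path.forward(x)
        y = y + (self.shortcut.forward(x) if self.shortcut is not None else x)
        return self.relu.forward(y)

    def backward(self, grad):
        g = self.relu.backward(grad)
        gx = self.path.backward(g)
        if self.shortcut is not None:
            gx = gx + self.shortcut.backward(g)
        else:
            gx = gx + g
        return gx


class _DecoderStage(Layer):
    """Upsample to the skip's size, concatenate, then two 3x3 conv-BN-ReLU."""

    def __init__(self, in_ch: int, skip_ch: int, out_ch: int, rng):
        self.resize = ResizeNearest()
        self.skip_ch = skip_ch
        self.block = Sequential(
            *_conv_bn_relu(in_ch + skip_ch, out_ch, 3, 1, rng).layers,
            *_conv_bn_relu(out_ch, out_ch, 3, 1, rng).layers,
        )

    def parameters(self):
        return self.block.parameters()

    def set_train(self, mode):
        self.train_mode = mode
        self.resize.set_train(mode)
        self.block.set_train(mode)

    def forward(self, x, skip, out_hw):
        x = self.resize.forward(x, out_hw)
        if skip is not None:
            x = np.concatenate([skip, x], axis=1)
        return self.block.forward(x)

    def backward(self, grad):
        g = self.block.backward(grad)
        if self.skip_ch:
            g_skip, g = g[:, :self.skip_ch], g[:, self.skip_ch:]
        else:
            g_skip = None
        return g_skip, self.resize.backward(np.ascontiguousarray(g))


class ResNetUNet:
    """Fully-convolutional residual-encoder U-net (NumPy implementation).

    ``forward`` maps an (N, 3, H, W) batch to (N, num_classes, H, W) scores
    for any H, W >= 32; after a forward pass ``deepest_shape`` holds the
    bottleneck spatial size (= ceil(H/32) x ceil(W/32)).
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        b = spec.base_width
        r1, r2, r3, r4 = spec.encoder_repeats

        self.stem = _conv_bn_relu(spec.in_channels, b, 7, 2, rng)
        self.pool = MaxPool2d(3, 2, 1)

        def stage(in_ch, width, out_ch, stride, repeats):
            blocks = [Bottleneck(in_ch, width, out_ch, stride, rng)]
            blocks += [Bottleneck(out_ch, width, out_ch, 1, rng) for _ in range(repeats - 1)]
            return blocks

        self.layer1 = stage(b, b, 4 * b, 1, r1)
        self.layer2 = stage(4 * b, 2 * b, 8 * b, 2, r2)
        self.layer3 = stage(8 * b, 4 * b, 16 * b, 2, r3)
        self.layer4 = stage(16 * b, 8 * b, 32 * b, 2, r4)

        dec = [max(4 * b, 1), max(2 * b, 1), max(b, 1), max(b // 2, 1), max(b // 4, 1)]
        skips = [16 * b, 8 * b, 4 * b, b, 0]
        ins = [32 * b] + dec[:-1]
        self.decoder = [
            _DecoderStage(i, s, o, rng) for i, s, o in zip(ins, skips, dec)
        ]
        self.head = Conv2d(dec[-1], spec.num_classes, 1, 1, bias=True, rng=rng)

        self._modules: list[Layer] = (
            [self.stem, self.pool] + self.layer1 + self.layer2 + self.layer3
            + self.layer4 + self.decoder + [self.head]
        )
        self.deepest_shape: tuple[int, int] | None = None
        self._sizes: list[tuple[int, int]] | None = None

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[Param]:
        return [p for m in self._modules for p in m.parameters()]

    def set_train(self, mode: bool) -> None:
        for m in self._modules:
            m.set_train(mode)

    def _bn_layers(self):
        out = []

        def walk(obj):
            if isinstance(obj, BatchNorm2d):
                out.append(obj)
            for attr in ("layers", "path", "shortcut", "block", "resize"):
                sub = getattr(obj, attr, None)
                if sub is None:
                    continue
                if isinstance(sub, list):
                    for s in sub:
                        walk(s)
                else:
                    walk(sub)
        for m in self._modules:
            walk(m)
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.value for i, p in enumerate(self.parameters())}
        for i, bn in enumerate(self._bn_layers()):
            state[f"bn_{i}_mean"] = bn.running_mean
            state[f"bn_{i}_var"] = bn.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            arr = np.asarray(state[f"param_{i}"], dtype=np.float32)
            if arr.shape != p.value.shape:
                raise ValueError(f"weight shape mismatch at param_{i}")
            p.value = arr.copy()
        for i, bn in enumerate(self._bn_layers()):
            bn.running_mean = np.asarray(state[f"bn_{i}_mean"], dtype=np.float32).copy()
            bn.running_var = np.asarray(state[f"bn_{i}_var"], dtype=np.float32).copy()

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != self.spec.in_channels:
            raise ValueError(f"expected (N, {self.spec.in_channels}, H, W) input")
        h, w = x.shape[2], x.shape[3]
        if h < MIN_INPUT_SIDE or w < MIN_INPUT_SIDE:
            raise ValueError(f"input too small: {h}x{w} (need >= {MIN_INPUT_SIDE})")

        c1 = self.stem.forward(x)
        y = self.pool.forward(c1)
        for blk in self.layer1:
            y = blk.forward(y)
        c2 = y
        for blk in self.layer2:
            y = blk.forward(y)
        c3 = y
        for blk in self.layer3:
            y = blk.forward(y)
        c4 = y
        for blk in self.layer4:
            y = blk.forward(y)
        c5 = y
        self.deepest_shape = (c5.shape[2], c5.shape[3])

        skips = [c4, c3, c2, c1, None]
        sizes = [c4.shape[2:], c3.shape[2:], c2.shape[2:], c1.shape[2:], (h, w)]
        self._sizes = sizes
        for stage, skip, size in zip(self.decoder, skips, sizes):
            y = stage.forward(y, skip, tuple(size))
        return self.head.forward(y)

    def predict_probs(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities (softmax over channels), eval mode."""
        self.set_train(False)
        return softmax_channels(self.forward(x))

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits)
        skip_grads: list[np.ndarray | None] = []
        for stage in reversed(self.decoder):
            g_skip, g = stage.backward(g)
            skip_grads.append(g_skip)
        skip_grads.reverse()  # grads for [c4, c3, c2, c1, None]
        g_c4, g_c3, g_c2, g_c1, _ = skip_grads

        for blk in reversed(self.layer4):
            g = blk.backward(g)
        g = g + g_c4
        for blk in reversed(self.layer3):
            g = blk.backward(g)
        g = g + g_c3
        for blk in reversed(self.layer2):
            g = blk.backward(g)
        g = g + g_c2
        for blk in reversed(self.layer1):
            g = blk.backward(g)
        g = self.pool.backward(g)
        g = g + g_c1
        self.stem.backward(g)


def build_model(spec: ModelSpec | None = None) -> ResNetUNet:
    """Construct a randomly initialized segmentation model from its spec."""
    return ResNetUNet(spec or ModelSpec())
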