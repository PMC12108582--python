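"""Training loop, stratified splitting and stack prediction.

The training recipe mirrors the segmentation study this package implements:
dice-coefficient loss on the softmax foreground probability, the Adam
optimizer (beta1 = 0.9, beta2 = 0.999, weight decay 1e-10), 100 epochs at
batch size 12 with an initial learning rate of 1e-4 that decays stepwise as
training advances. All defaults are configurable; the step-decay factor and
interval are this package's documented concretization of a "gradually
decreasing" schedule.
"""
from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from ..grids import LabelMask, VoxelGrid
from .layers import Adam, dice_loss_grad, softmax_channels
from .resunet import MIN_INPUT_SIDE, ModelSpec, ResNetUNet

#: Intensity scale divisor applied to input slices (8-bit-like exports).
INPUT_SCALE = 255.0


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 12
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 1e-10
    lr_decay_factor: float = 0.5
    lr_decay_every: int = 25
    seed: int = 0
    pretrained_encoder: str | os.PathLike | None = None
    #: probability cutoff equivalent to the default argmax binarization
    threshold: float = 0.5

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        for name in ("learning_rate", "beta1", "beta2", "weight_decay", "lr_decay_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def split_stratified(
    items: Sequence,
    train_fraction: float,
    seed: int = 0,
    tag: Callable | Sequence | None = None,
) -> tuple[list, list]:
    """Split items into train/validation sets, stratified by compartment tag.

    ``tag`` may be a callable, a parallel sequence of labels, or ``None``
    (items then carry a ``compartment`` attribute or are ``(item, tag)``
    pairs). The global train size is ``round(train_fraction * n)`` and is
    allocated to strata by largest remainder, so each stratum's proportion
    matches the whole within one item. Deterministic per seed.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    items = list(items)
    if not items:
        raise ValueError("cannot split an empty set")

    if tag is None:
        tags = [getattr(it, "compartment", None) or it[1] for it in items]
    elif callable(tag):
        tags = [tag(it) for it in items]
    else:
        tags = list(tag)
        if len(tags) != len(items):
            raise ValueError("tag sequence length must match items")

    strata: dict = {}
    for idx, t in enumerate(tags):
        strata.setdefault(t, []).append(idx)

    n = len(items)
    n_train = int(round(train_fraction * n))
    keys = sorted(strata, key=str)
    quotas = {k: train_fraction * len(strata[k]) for k in keys}
    base = {k: int(np.floor(quotas[k])) for k in keys}
    short = n_train - sum(base.values())
    # hand out the remaining slots to the largest fractional remainders
    order = sorted(keys, key=lambda k: (quotas[k] - base[k], str(k)), reverse=True)
    for k in order[:max(short, 0)]:
        base[k] += 1

    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    for k in keys:
        idxs = np.array(strata[k])
        rng.shuffle(idxs)
        take = min(base[k], len(idxs))
        train_idx += idxs[:take].tolist()
        val_idx += idxs[take:].tolist()
    return [items[i] for i in sorted(train_idx)], [items[i] for i in sorted(val_idx)]


def _prepare_images(images: np.ndarray) -> np.ndarray:
    """(N, H, W) grayscale -> (N, 3, H, W) float32 in [0, ~1]."""
    x = np.asarray(images, dtype=np.float32) / INPUT_SCALE
    return np.repeat(x[:, None], 3, axis=1)


def train(
    model: ResNetUNet,
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig,
    log: Callable[[str], None] | None = None,
) -> list[float]:
    """Train a segmentation model on (slice image, binary mask) pairs.

    Returns the per-epoch mean dice loss history (length = ``epochs``).
    Reproducible for a fixed seed/config on one platform.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty training set")
    shapes = {p[0].shape for p in pairs}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent pair shapes: {sorted(shapes)}")
    for img, msk in pairs:
        if img.shape != msk.shape:
            raise ValueError("image/mask shape mismatch in training pair")

    if config.pretrained_encoder is not None:
        load_weights(model, config.pretrained_encoder)

    params = model.parameters()
    opt = Adam(params, lr=config.learning_rate, beta1=config.beta1,
               beta2=config.beta2, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    history: list[float] = []

    images = np.stack([p[0] for p in pairs]) if pairs else np.empty((0,))
    masks = np.stack([p[1] for p in pairs]).astype(np.float32) if pairs else np.empty((0,))

    for epoch in range(config.epochs):
        opt.lr = config.learning_rate * config.lr_decay_factor ** (epoch // config.lr_decay_every)
        order = rng.permutation(len(pairs))
        losses = []
        model.set_train(True)
        for start in range(0, len(pairs), config.batch_size):
            idx = order[start:start + config.batch_size]
            x = _prepare_images(images[idx])
            t = masks[idx]
            logits = model.forward(x)
            probs = softmax_channels(logits)
            p_fg = probs[:, 1]
            loss, dldp = dice_loss_grad(p_fg, t)
            # softmax backward for the 2-class case
            dlogits = np.zeros_like(logits)
            dlogits[:, 1] = dldp * p_fg * probs[:, 0]
            dlogits[:, 0] = -dldp * p_fg * probs[:, 0]
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        epoch_loss = float(np.mean(losses))
        history.append(epoch_loss)
        if log is not None:
            log(f"epoch {epoch + 1}/{config.epochs} lr {opt.lr:.2e} dice_loss {epoch_loss:.4f}")
    model.set_train(False)
    return history


def predict_stack(model: ResNetUNet, grid: VoxelGrid,
                  batch_size: int = 4) -> LabelMask:
    """Segment every slice of a CT stack; per-pixel class = argmax.

    Output mask shape equals the grid shape.
    """
    n_slices, h, w = grid.shape
    if h < MIN_INPUT_SIDE or w < MIN_INPUT_SIDE:
        raise ValueError(f"input too small: slices are {h}x{w} (need >= {MIN_INPUT_SIDE})")
    model.set_train(False)
    out = np.zeros(grid.shape, dtype=np.uint8)
    for start in range(0, n_slices, batch_size):
        x = _prepare_images(grid.intensities[start:start + batch_size])
        logits = model.forward(x)
        out[start:start + x.shape[0]] = np.argmax(logits, axis=1).astype(np.uint8)
    return LabelMask(out)


def save_weights(model: ResNetUNet, path: str | os.PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, **model.state_dict())


def load_weights(model: ResNetUNet, path: str | os.PathLike) -> None:
    with np.load(path) as data:
        model.load_state_dict(dict(data))
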