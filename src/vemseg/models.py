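"""Segmentation architectures: residual U-Net and UNet++ (nested skips).

Both are size-parameterized encoder–decoder networks mapping a grayscale crop
``(B, 1, H, W)`` to per-pixel class scores ``(B, n_classes, H, W)``; the
softmax over classes is the network's confidence map. The residual U-Net uses
residual blocks at every scale with strided-convolution downsampling. UNet++
adds dense convolution blocks on the skip connections and, with deep
supervision, one segmentation head per decoder branch; the reported
confidence is the arithmetic mean of all branch confidences while the
individual branch outputs remain available for the deep-supervision loss.

Defaults are small enough to train on a CPU; the sizes used in large-scale
work (millions of parameters) are reachable through ``base_width``/``depth``
but are not the tested regime.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autograd import (
    Adam,
    BatchNorm2d,
    Conv2d,
    Module,
    Tensor,
    concat,
    max_pool2x2,
    softmax,
    upsample_nearest2x,
)
from .losses import DEFAULT_DICE_EPS, batch_soft_dice_loss

__all__ = [
    "ModelConfig",
    "build_model",
    "ResUNet",
    "UNetPlusPlus",
    "deep_supervision_loss",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    arch: str = "resunet"  # "resunet" | "unetpp"
    in_channels: int = 1
    n_classes: int = 2
    base_width: int = 8
    depth: int = 3
    deep_supervision: bool = True  # unetpp only

    def validate(self) -> None:
        if self.arch not in ("resunet", "unetpp"):
            raise ValueError(f"unknown arch {self.arch!r}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_width < 1 or self.in_channels < 1:
            raise ValueError("base_width and in_channels must be >= 1")


def build_model(cfg: ModelConfig, seed: int = 0) -> "SegmentationNet":
    """Construct a network with weights initialized from ``seed``."""
    cfg.validate()
    rng = np.random.default_rng([int(seed), 7])
    if cfg.arch == "resunet":
        return ResUNet(cfg, rng)
    return UNetPlusPlus(cfg, rng)


class SegmentationNet(Module):
    """Common surface: ``forward`` -> logits, ``confidences`` -> softmax map;
    ``branch_confidences`` exposes the deep-supervision branches (a single
    branch for architectures without them)."""

    config: ModelConfig

    def _check_input(self, x: Tensor) -> None:
        B, C, H, W = x.shape
        if C != self.config.in_channels:
            raise ValueError(f"expected {self.config.in_channels} channels, got {C}")
        div = 2 ** (self.config.depth - 1)
        if H % div or W % div:
            raise ValueError(
                f"input {H}x{W} not divisible by 2^(depth-1) = {div}"
            )

    def confidences(self, x: Tensor) -> Tensor:
        branches = self.branch_confidences(x)
        out = branches[0]
        for b in branches[1:]:
            out = out + b
        return out * (1.0 / len(branches))

    def branch_confidences(self, x: Tensor) -> list[Tensor]:
        raise NotImplementedError


class _ConvBNReLU(Module):
    def __init__(self, cin, cout, rng, kernel=3, stride=1):
        super().__init__()
        self.conv = Conv2d(cin, cout, kernel, rng, stride=stride)
        self.bn = BatchNorm2d(cout)

    def forward(self, x):
        return self.bn(self.conv(x)).relu()


class _ResBlock(Module):
    """conv-BN-ReLU-conv-BN plus identity, ReLU after the sum."""

    def __init__(self, ch, rng):
        super().__init__()
        self.conv1 = Conv2d(ch, ch, 3, rng)
        self.bn1 = BatchNorm2d(ch)
        self.conv2 = Conv2d(ch, ch, 3, rng)
        self.bn2 = BatchNorm2d(ch)

    def forward(self, x):
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        return (h + x).relu()


class ResUNet(SegmentationNet):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = cfg
        w = [cfg.base_width * 2**i for i in range(cfg.depth)]
        self.stem = _ConvBNReLU(cfg.in_channels, w[0], rng)
        self.enc = [_ResBlock(w[i], rng) for i in range(cfg.depth)]
        self.down = [
            _ConvBNReLU(w[i], w[i + 1], rng, stride=2)
            for i in range(cfg.depth - 1)
        ]
        self.up_proj = [
            Conv2d(w[i + 1], w[i], 1, rng) for i in range(cfg.depth - 1)
        ]
        self.dec_fuse = [
            _ConvBNReLU(2 * w[i], w[i], rng) for i in range(cfg.depth - 1)
        ]
        self.dec = [_ResBlock(w[i], rng) for i in range(cfg.depth - 1)]
        self.head = Conv2d(w[0], cfg.n_classes, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        self._check_input(x)
        skips = []
        h = self.stem(x)
        for i in range(self.config.depth):
            h = self.enc[i](h)
            if i < self.config.depth - 1:
                skips.append(h)
                h = self.down[i](h)
        for i in reversed(range(self.config.depth - 1)):
            h = self.up_proj[i](upsample_nearest2x(h))
            h = self.dec_fuse[i](concat([h, skips[i]], axis=1))
            h = self.dec[i](h)
        return self.head(h)

    def branch_confidences(self, x: Tensor) -> list[Tensor]:
        return [softmax(self.forward(x), axis=1)]


class UNetPlusPlus(SegmentationNet):
    """Nested U-Net: node X[i][j] fuses all same-level predecessors with the
    upsampled node one level below; heads sit on X[0][1..depth-1]."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = cfg
        d = cfg.depth
        w = [cfg.base_width * 2**i for i in range(d)]
        self.blocks = []  # flattened [(i, j, block)] to keep Module discovery simple
        self._index: dict[tuple[int, int], int] = {}
        for i in range(d):
            cin = cfg.in_channels if i == 0 else w[i - 1]
            self._add(i, 0, _DoubleConv(cin, w[i], rng))
        for j in range(1, d):
            for i in range(d - j):
                cin = j * w[i] + w[i + 1]
                self._add(i, j, _DoubleConv(cin, w[i], rng))
        n_heads = (d - 1) if cfg.deep_supervision else 1
        self.heads = [Conv2d(w[0], cfg.n_classes, 1, rng) for _ in range(n_heads)]

    def _add(self, i, j, block):
        self._index[(i, j)] = len(self.blocks)
        self.blocks.append(block)

    def _node(self, i, j):
        return self.blocks[self._index[(i, j)]]

    def forward_branches(self, x: Tensor) -> list[Tensor]:
        self._check_input(x)
        d = self.config.depth
        X: dict[tuple[int, int], Tensor] = {}
        h = x
        for i in range(d):
            if i > 0:
                h = max_pool2x2(h)
            h = self._node(i, 0)(h)
            X[(i, 0)] = h
        for j in range(1, d):
            for i in range(d - j):
                inputs = [X[(i, k)] for k in range(j)]
                inputs.append(upsample_nearest2x(X[(i + 1, j - 1)]))
                X[(i, j)] = self._node(i, j)(concat(inputs, axis=1))
        if self.config.deep_supervision:
            return [self.heads[j - 1](X[(0, j)]) for j in range(1, d)]
        return [self.heads[0](X[(0, d - 1)])]

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_branches(x)[-1]

    def branch_confidences(self, x: Tensor) -> list[Tensor]:
        return [softmax(b, axis=1) for b in self.forward_branches(x)]


class _DoubleConv(Module):
    def __init__(self, cin, cout, rng):
        super().__init__()
        self.a = _ConvBNReLU(cin, cout, rng)
        self.b = _ConvBNReLU(cout, cout, rng)

    def forward(self, x):
        return self.b(self.a(x))


def deep_supervision_loss(
    branch_confidences: list[Tensor],
    label: np.ndarray,
    eps: float = DEFAULT_DICE_EPS,
):
    """Mean over segmentation branches of the per-crop soft Dice loss of each
    branch's foreground confidence against the label."""
    if not branch_confidences:
        raise ValueError("need at least one branch")
    total = batch_soft_dice_loss(label, branch_confidences[0][:, 1], eps)
    for b in branch_confidences[1:]:
        total = total + batch_soft_dice_loss(label, b[:, 1], eps)
    return total * (1.0 / len(branch_confidences))


def save_checkpoint(
    path, net: SegmentationNet, step: int = 0, seed: int = 0, optimizer: Adam | None = None
) -> Path:
    """Single-file checkpoint: weights + config + training step + seed."""
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"config": asdict(net.config), "step": int(step), "seed": int(seed)}
    payload = {f"param/{k}": v for k, v in net.state_dict().items()}
    payload["meta"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    )
    if optimizer is not None:
        payload["opt/t"] = np.array(optimizer.t)
        for i, (m, v) in enumerate(zip(optimizer.m, optimizer.v)):
            payload[f"opt/m{i}"] = m
            payload[f"opt/v{i}"] = v
    np.savez(path, **payload)
    return path


def load_checkpoint(path) -> tuple[SegmentationNet, dict]:
    path = Path(path)
    if not path.exists() and path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        cfg = ModelConfig(**meta["config"])
        net = build_model(cfg, seed=meta["seed"])
        state = {
            k[len("param/") :]: data[k] for k in data.files if k.startswith("param/")
        }
    net.load_state_dict(state)
    return net, meta
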