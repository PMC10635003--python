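"""Training losses: soft Dice, cross pseudo supervision (CPS), CutMix.

The supervised objective is the smoothed soft Dice loss

    DL(y, p) = 1 - (2 * sum(y * p) + eps) / (sum(y) + sum(p) + eps),

which directly optimizes the evaluation metric and behaves well under heavy
class imbalance; with ``eps > 0`` an empty prediction of an empty target is a
perfect score.

The semi-supervised term trains two networks that supervise each other: each
network's per-pixel argmax (its *pseudo-label map*) becomes a hard training
target for the peer, with gradients stopped through the pseudo-labels, and
the per-pixel cross-entropy of the original formulation replaced by the same
soft Dice loss. The CPS weight lambda ramps up linearly from 0 so that early
training is driven purely by the labeled slices. CutMix pastes a rectangle of
one crop into another; pseudo-labels for a mixed crop are assembled from the
pseudo-labels of the two unmixed crops using the same rectangle mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .autograd import Tensor, as_tensor

__all__ = [
    "soft_dice_loss",
    "batch_soft_dice_loss",
    "pseudo_label",
    "cps_loss",
    "cps_loss_from_pseudo",
    "WarmupSchedule",
    "lambda_at",
    "CutMixBox",
    "sample_cutmix_box",
    "cutmix_apply",
    "mix_with_mask",
]

DEFAULT_DICE_EPS = 1.0


def soft_dice_loss(y, p, eps: float = DEFAULT_DICE_EPS):
    """Smoothed soft Dice loss over the whole array (scalar in [0, 1]).

    ``y`` is a binary target, ``p`` a [0, 1] foreground confidence of the same
    shape; either may be a plain ndarray or an autograd :class:`Tensor` (the
    returned Tensor is differentiable w.r.t. whichever inputs carry a tape).
    """
    y = as_tensor(y)
    p = as_tensor(p)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: target {y.shape} vs prediction {p.shape}")
    num = (y * p).sum() * 2.0 + eps
    den = y.sum() + p.sum() + eps
    return 1.0 - num / den


def batch_soft_dice_loss(y, p, eps: float = DEFAULT_DICE_EPS):
    """Per-crop soft Dice losses averaged over the batch.

    ``y``: (B, H, W) binary, ``p``: (B, H, W) foreground confidences.
    """
    y = as_tensor(y)
    p = as_tensor(p)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: target {y.shape} vs prediction {p.shape}")
    axes = tuple(range(1, len(y.shape)))
    num = (y * p).sum(axis=axes) * 2.0 + eps
    den = y.sum(axis=axes) + p.sum(axis=axes) + eps
    return (1.0 - num / den).mean()


def pseudo_label(conf) -> np.ndarray:
    """Hard per-pixel class map from a confidence map: argmax over the class
    axis, ties resolved toward the lower class index (background). The result
    is a plain integer array — constant w.r.t. optimization (stop-gradient).
    """
    data = conf.data if isinstance(conf, Tensor) else np.asarray(conf)
    if data.ndim not in (3, 4):
        raise ValueError(
            f"confidence map must be (C, H, W) or (B, C, H, W), got {data.shape}"
        )
    axis = 0 if data.ndim == 3 else 1
    return np.argmax(data, axis=axis)  # np.argmax takes the first (lowest) max


def cps_loss_from_pseudo(
    conf1: Tensor,
    conf2: Tensor,
    pl1: np.ndarray,
    pl2: np.ndarray,
    eps: float = DEFAULT_DICE_EPS,
):
    """CPS loss given precomputed pseudo-label maps (used by the CutMix path,
    where pseudo-labels come from the unmixed inputs)."""
    if conf1.shape != conf2.shape:
        raise ValueError(f"shape mismatch: {conf1.shape} vs {conf2.shape}")
    if conf1.shape[1] != 2:
        raise ValueError("CPS with Dice substitution expects 2-class confidences")
    fg1 = (np.asarray(pl1) == 1).astype(np.float32)
    fg2 = (np.asarray(pl2) == 1).astype(np.float32)
    return batch_soft_dice_loss(fg2, conf1[:, 1], eps) + batch_soft_dice_loss(
        fg1, conf2[:, 1], eps
    )


def cps_loss(conf1: Tensor, conf2: Tensor, eps: float = DEFAULT_DICE_EPS):
    """Cross pseudo supervision loss with the Dice substitution.

    Each direction treats the *other* network's pseudo-label map as a fixed
    binary target for its own foreground confidence; the two per-crop Dice
    losses are summed and averaged over the batch. Symmetric in its arguments,
    and no gradient flows into the network that produced a pseudo-label.
    """
    conf1, conf2 = as_tensor(conf1), as_tensor(conf2)
    return cps_loss_from_pseudo(
        conf1, conf2, pseudo_label(conf1), pseudo_label(conf2), eps
    )


@dataclass
class WarmupSchedule:
    """Linear ramp of the CPS weight: 0 at step 0, ``lambda_max`` from
    ``warmup_steps`` on (immediately when ``warmup_steps == 0``)."""

    lambda_max: float = 1.0
    warmup_steps: int = 0

    def __post_init__(self):
        if self.warmup_steps < 0:
            raise ValueError("warmup_steps must be >= 0")


def lambda_at(step: int, schedule: WarmupSchedule) -> float:
    if step < 0:
        raise ValueError("step must be >= 0")
    if schedule.warmup_steps == 0:
        return float(schedule.lambda_max)
    return float(schedule.lambda_max) * min(1.0, step / schedule.warmup_steps)


class CutMixBox(NamedTuple):
    """Rectangle (top, left, height, width) fully inside the crop."""

    y0: int
    x0: int
    h: int
    w: int


def sample_cutmix_box(crop_size: int, rng: np.random.Generator) -> CutMixBox:
    """Draw a box whose area ratio follows the uniform distribution on (0, 1)
    (CutMix with Beta(1, 1)); the square box is then placed uniformly among
    the positions where it fits entirely inside the crop."""
    if crop_size < 1:
        raise ValueError("crop_size must be >= 1")
    ratio = rng.random()
    side = min(int(round(crop_size * np.sqrt(ratio))), crop_size)
    y0 = int(rng.integers(0, crop_size - side + 1))
    x0 = int(rng.integers(0, crop_size - side + 1))
    return CutMixBox(y0, x0, side, side)


def _box_mask(crop_size: int, box: CutMixBox) -> np.ndarray:
    y0, x0, h, w = box
    if h < 0 or w < 0 or y0 < 0 or x0 < 0 or y0 + h > crop_size or x0 + w > crop_size:
        raise ValueError(f"box {box} not inside a {crop_size}-pixel crop")
    m = np.zeros((crop_size, crop_size), dtype=np.float32)
    m[y0 : y0 + h, x0 : x0 + w] = 1.0
    return m


def mix_with_mask(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Pixels from ``b`` where the mask is set, from ``a`` elsewhere. The mask
    broadcasts over any leading axes of the batches."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"batch shapes differ: {a.shape} vs {b.shape}")
    m = np.asarray(mask)
    m = m.reshape(m.shape[: -2] + (1,) * (a.ndim - m.ndim) + m.shape[-2:])
    mixed = a * (1 - m) + b * m
    return mixed.astype(a.dtype) if a.dtype != np.float64 else mixed


def cutmix_apply(
    batch_a: np.ndarray,
    batch_b: np.ndarray,
    box: CutMixBox | list[CutMixBox],
) -> tuple[np.ndarray, np.ndarray]:
    """CutMix two congruent batches: output takes ``batch_b`` inside the box
    and ``batch_a`` outside. Accepts one box for the whole batch or one per
    item; returns the mixed batch and the binary mix-mask ((B, H, W) when
    per-item boxes are given, else (H, W)).

    Labels or pseudo-labels for the mixed batch must be produced by mixing the
    labels of the two *unmixed* batches with the same mask.
    """
    batch_a, batch_b = np.asarray(batch_a), np.asarray(batch_b)
    if batch_a.shape != batch_b.shape:
        raise ValueError(f"batch shapes differ: {batch_a.shape} vs {batch_b.shape}")
    crop = batch_a.shape[-1]
    if batch_a.shape[-2] != crop:
        raise ValueError("crops must be square")
    if isinstance(box, CutMixBox):
        mask = _box_mask(crop, box)
    else:
        if len(box) != batch_a.shape[0]:
            raise ValueError("need one box per batch item")
        mask = np.stack([_box_mask(crop, b) for b in box])
    return mix_with_mask(batch_a, batch_b, mask), mask
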