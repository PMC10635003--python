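"""Training-data pipeline: slice selection, context tiling, crops, augmentation.

Only a small evenly-spaced subset of slices carries trusted labels. Training
crops are cut from those slices as large *context windows* that are block-
averaged down to the network input size, so each crop sees a wide field of
view at reduced resolution. Because nucleoli cover a tiny fraction of the
image, plain uniform cropping yields almost only background and the model
collapses; the sampler therefore guarantees a configurable fraction of crops
containing foreground by re-centering rejected crops on a random foreground
pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .volume_io import AnnotatedVolume

__all__ = [
    "SamplerConfig",
    "CropBatch",
    "select_labeled_slices",
    "extract_context_tile",
    "downsample_labels",
    "sample_training_batch",
    "sample_crops",
    "augment",
    "dihedral",
]

_RECENTER_RETRIES = 50


@dataclass
class SamplerConfig:
    """Crop geometry and sampling behaviour.

    ``context_size`` is the side of the window cut at native resolution and
    ``out_size`` the side after block-average downsampling; their ratio is the
    downsampling factor (2048 -> 512 gives factor 4). ``foreground_fraction``
    is the expected fraction of crops that must contain at least one
    foreground pixel after downsampling.
    """

    context_size: int = 2048
    out_size: int = 512
    foreground_fraction: float = 0.0
    augment: bool = False
    rng_seed: int = 0
    slice_spacing: str = "centered"  # or "endpoint"

    def validate(self) -> None:
        if self.out_size < 1 or self.context_size < self.out_size:
            raise ValueError(
                f"context_size {self.context_size} must be >= out_size {self.out_size}"
            )
        if self.context_size % self.out_size:
            raise ValueError(
                f"context_size {self.context_size} not divisible by out_size {self.out_size}"
            )
        if not 0.0 <= self.foreground_fraction <= 1.0:
            raise ValueError(
                f"foreground_fraction {self.foreground_fraction} outside [0, 1]"
            )
        if self.slice_spacing not in ("centered", "endpoint"):
            raise ValueError(f"unknown slice_spacing {self.slice_spacing!r}")

    @property
    def factor(self) -> int:
        return self.context_size // self.out_size


@dataclass
class CropBatch:
    """A batch of 2-D crops ready for the network.

    ``provenance`` records, per item, the source slice and window anchor
    ``(z, y0, x0, downsample_factor)``; ``has_foreground`` flags items whose
    (downsampled) label contains at least one foreground pixel.
    """

    images: np.ndarray  # (B, 1, H, W) float32 in [0, 1]
    labels: np.ndarray | None  # (B, H, W) uint8 or None
    provenance: list[tuple[int, int, int, int]] = field(default_factory=list)
    has_foreground: np.ndarray | None = None  # (B,) bool

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        if self.images.ndim != 4 or self.images.shape[1] != 1:
            raise ValueError(f"images must be (B, 1, H, W), got {self.images.shape}")
        if self.images.shape[2] != self.images.shape[3]:
            raise ValueError("crops must be square")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.uint8)
            fg = self.labels.reshape(len(self.labels), -1).any(axis=1)
            if self.has_foreground is None:
                self.has_foreground = fg
            elif not np.array_equal(np.asarray(self.has_foreground), fg):
                raise ValueError("has_foreground inconsistent with labels")

    def __len__(self) -> int:
        return int(self.images.shape[0])


def select_labeled_slices(
    n_train: int, n_slices: int, spacing: str = "centered"
) -> np.ndarray:
    """Evenly-spaced training slice indices.

    The default convention places slices at centered quantiles,
    ``i_k = floor((k + 0.5) * n_slices / n_train)``, so the gaps between
    consecutive picks (and to the volume ends) differ by at most one slice.
    ``spacing='endpoint'`` instead includes both volume ends.
    """
    if not 1 <= n_train <= n_slices:
        raise ValueError(f"n_train {n_train} outside [1, {n_slices}]")
    if spacing == "centered":
        idx = np.floor((np.arange(n_train) + 0.5) * n_slices / n_train)
    elif spacing == "endpoint":
        if n_train == 1:
            idx = np.array([(n_slices - 1) // 2])
        else:
            idx = np.round(np.arange(n_train) * (n_slices - 1) / (n_train - 1))
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    return idx.astype(np.int64)


def _padded_window(img: np.ndarray, y0: int, x0: int, size: int) -> np.ndarray:
    """Window of ``size``² anchored (top-left) at (y0, x0); out-of-bounds
    regions are reflect-padded (edge-padded if the image is smaller than the
    reflection allows)."""
    H, W = img.shape
    ys, ye = y0, y0 + size
    xs, xe = x0, x0 + size
    win = img[max(0, ys) : max(0, min(H, ye)), max(0, xs) : max(0, min(W, xe))]
    pads = (
        (max(0, -ys), max(0, ye - H)),
        (max(0, -xs), max(0, xe - W)),
    )
    if any(p for pair in pads for p in pair):
        h, w = win.shape
        if h == 0 or w == 0:
            raise ValueError(
                f"window ({y0},{x0})+{size} does not intersect image {img.shape}"
            )
        mode = "reflect" if min(h, w) > max(p for pair in pads for p in pair) else "edge"
        win = np.pad(win, pads, mode=mode)
    return win


def _block_mean(window: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return window.astype(np.float32)
    h, w = window.shape
    return (
        window.reshape(h // factor, factor, w // factor, factor)
        .astype(np.float32)
        .mean(axis=(1, 3))
    )


def extract_context_tile(
    slice_image: np.ndarray, y0: int, x0: int, cfg: SamplerConfig
) -> np.ndarray:
    """Cut a ``context_size``² window anchored at (y0, x0) and block-average
    it down to ``out_size``² — wide field of view at reduced resolution."""
    cfg.validate()
    win = _padded_window(np.asarray(slice_image), y0, x0, cfg.context_size)
    return _block_mean(win, cfg.factor)


def downsample_labels(
    label_window: np.ndarray, factor: int, threshold: float = 0.5
) -> np.ndarray:
    """Block-mean then threshold; a block exactly at the threshold counts as
    foreground (ties -> foreground)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    m = _block_mean(np.asarray(label_window, dtype=np.float32), factor)
    return (m >= threshold).astype(np.uint8)


def _anchor_bounds(dim: int, context: int) -> int:
    return max(dim - context, 0)


def sample_crops(
    intensities: np.ndarray,
    masks: np.ndarray | None,
    slices,
    batch_size: int,
    cfg: SamplerConfig,
    rng: np.random.Generator,
    foreground_fraction: float | None = None,
) -> CropBatch:
    """Draw random context crops from the given slice pool.

    ``masks`` supplies the foreground used both for crop labels and for the
    foreground guarantee; pass ``None`` for unlabeled crops (no labels, no
    guarantee). Items that must contain foreground are re-drawn up to a retry
    cap, re-centered (with jitter) on a random foreground pixel of a random
    foreground-bearing slice.
    """
    cfg.validate()
    slices = np.asarray(list(slices), dtype=np.int64)
    if len(slices) == 0:
        raise ValueError("empty slice pool")
    fg_frac = cfg.foreground_fraction if foreground_fraction is None else foreground_fraction
    Z, H, W = intensities.shape
    cs, f = cfg.context_size, cfg.factor
    ymax, xmax = _anchor_bounds(H, cs), _anchor_bounds(W, cs)

    fg_slices = None
    fg_pixels: dict[int, np.ndarray] = {}
    if masks is not None and fg_frac > 0:
        fg_slices = np.array([z for z in slices if masks[z].any()], dtype=np.int64)
        if len(fg_slices) == 0:
            raise ValueError(
                "foreground_fraction > 0 but no slice in the pool contains foreground"
            )

    images = np.empty((batch_size, 1, cfg.out_size, cfg.out_size), dtype=np.float32)
    labels = (
        np.empty((batch_size, cfg.out_size, cfg.out_size), dtype=np.uint8)
        if masks is not None
        else None
    )
    provenance: list[tuple[int, int, int, int]] = []

    # fixed quota of guaranteed-foreground items (shuffled positions), so the
    # realized fraction is at least the configured one, not just on average
    enforce_flags = np.zeros(batch_size, dtype=bool)
    if masks is not None and fg_frac > 0:
        quota = min(batch_size, int(np.ceil(fg_frac * batch_size)))
        enforce_flags[:quota] = True
        rng.shuffle(enforce_flags)

    for b in range(batch_size):
        enforce = bool(enforce_flags[b])
        z = int(rng.choice(slices))
        y0 = int(rng.integers(0, ymax + 1))
        x0 = int(rng.integers(0, xmax + 1))
        lab = None
        if masks is not None:
            lab = downsample_labels(
                _padded_window(masks[z], y0, x0, cs), f
            )
        if enforce and lab is not None and not lab.any():
            for _ in range(_RECENTER_RETRIES):
                z = int(rng.choice(fg_slices))
                if z not in fg_pixels:
                    fg_pixels[z] = np.argwhere(masks[z] > 0)
                py, px = fg_pixels[z][rng.integers(0, len(fg_pixels[z]))]
                jy = int(rng.integers(-cs // 4, cs // 4 + 1))
                jx = int(rng.integers(-cs // 4, cs // 4 + 1))
                y0 = int(np.clip(py - cs // 2 + jy, -cs // 2, H - cs // 2))
                x0 = int(np.clip(px - cs // 2 + jx, -cs // 2, W - cs // 2))
                lab = downsample_labels(_padded_window(masks[z], y0, x0, cs), f)
                if lab.any():
                    break
        images[b, 0] = extract_context_tile(intensities[z], y0, x0, cfg)
        if labels is not None:
            labels[b] = lab
        provenance.append((z, y0, x0, f))

    batch = CropBatch(images=images, labels=labels, provenance=provenance)
    if batch.has_foreground is None:
        batch.has_foreground = np.zeros(batch_size, dtype=bool)
    if cfg.augment:
        batch = augment(batch, rng)
    return batch


def sample_training_batch(
    volume: AnnotatedVolume,
    structure: str,
    batch_size: int,
    cfg: SamplerConfig,
    rng: np.random.Generator | None = None,
) -> CropBatch:
    """Supervised batch: crops drawn only from the volume's trusted slices,
    with the configured foreground guarantee for the given structure."""
    if not volume.labeled_slices:
        raise ValueError("volume has no labeled slices")
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    return sample_crops(
        volume.intensities,
        volume.labels[structure],
        volume.labeled_slices,
        batch_size,
        cfg,
        rng,
    )


def dihedral(arr: np.ndarray, t: int) -> np.ndarray:
    """Apply one of the 8 symmetries of the square to the trailing two axes:
    t % 4 right-angle rotations, mirrored first if t >= 4."""
    if not 0 <= t < 8:
        raise ValueError("dihedral index must be in [0, 8)")
    out = np.flip(arr, axis=-1) if t >= 4 else arr
    return np.rot90(out, k=t % 4, axes=(-2, -1))


def augment(batch: CropBatch, rng: np.random.Generator) -> CropBatch:
    """Each item independently receives one of the 8 dihedral transforms
    (identity, right-angle rotations, mirrored versions), applied identically
    to image and label. Foreground pixel counts are invariant."""
    B = len(batch)
    ts = rng.integers(0, 8, size=B)
    images = np.stack(
        [dihedral(batch.images[i], int(ts[i])) for i in range(B)]
    ).astype(np.float32)
    labels = None
    if batch.labels is not None:
        labels = np.stack(
            [dihedral(batch.labels[i], int(ts[i])) for i in range(B)]
        ).astype(np.uint8)
    return CropBatch(
        images=images,
        labels=labels,
        provenance=list(batch.provenance),
        has_foreground=None if labels is not None else batch.has_foreground,
    )
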