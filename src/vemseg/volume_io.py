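"""Reading and writing annotated image stacks.

A volume is a Z-stack of single-channel slices; stacks are stored either as a
multi-page TIFF (z = page index) or a directory of per-slice TIFF/PNG files
sorted lexicographically. Label stacks are binary per structure and stored as
0/255. The coordinate convention everywhere is ``(z, y, x)``, 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

logger = logging.getLogger("vemseg")

__all__ = [
    "AnnotatedVolume",
    "read_stack",
    "read_volume",
    "write_prediction",
    "write_intensities",
    "load_labeled_slices",
]

_STACK_SUFFIXES = (".tif", ".tiff", ".png")


@dataclass
class AnnotatedVolume:
    """A grayscale stack plus per-structure binary labels.

    ``labeled_slices`` is the sorted set of z indices whose labels are trusted
    for supervised training; everything else is the unlabeled pool the
    semi-supervised loss draws from.
    """

    intensities: np.ndarray
    labels: dict[str, np.ndarray] = field(default_factory=dict)
    labeled_slices: list[int] = field(default_factory=list)
    voxel_size_nm: tuple[float, float, float] | None = None

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"intensities must be (Z, Y, X), got shape {self.intensities.shape}"
            )
        for name, lab in self.labels.items():
            lab = np.asarray(lab)
            if lab.shape != self.intensities.shape:
                raise ValueError(
                    f"label '{name}' shape {lab.shape} does not match "
                    f"intensities shape {self.intensities.shape}"
                )
            vals = np.unique(lab)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(
                    f"label '{name}' must be binary 0/1, found values {vals[:5]}"
                )
            self.labels[name] = lab.astype(np.uint8)
        zmax = self.intensities.shape[0]
        sl = sorted({int(z) for z in self.labeled_slices})
        if sl and (sl[0] < 0 or sl[-1] >= zmax):
            raise ValueError(
                f"labeled_slices {sl[0]}..{sl[-1]} outside [0, {zmax})"
            )
        self.labeled_slices = sl

    @property
    def n_slices(self) -> int:
        return int(self.intensities.shape[0])

    @property
    def unlabeled_slices(self) -> list[int]:
        sel = set(self.labeled_slices)
        return [z for z in range(self.n_slices) if z not in sel]

    def with_labeled_slices(self, slices) -> "AnnotatedVolume":
        """Same data, different trusted-slice set (no copy of the arrays)."""
        return AnnotatedVolume(
            intensities=self.intensities,
            labels=dict(self.labels),
            labeled_slices=list(slices),
            voxel_size_nm=self.voxel_size_nm,
        )


def _read_one(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return iio.imread(path)


def read_stack(path) -> np.ndarray:
    """Read a Z-stack from a multi-page TIFF or a directory of slice images
    (sorted lexicographically). Returns (Z, Y, X)."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _STACK_SUFFIXES
        )
        if not files:
            raise FileNotFoundError(f"no slice images found in {path}")
        slices = []
        for i, f in enumerate(files):
            try:
                slices.append(np.asarray(_read_one(f)))
            except Exception as exc:  # pragma: no cover - corrupt input
                raise IOError(f"unreadable slice {i} ({f.name}): {exc}") from exc
        shapes = {s.shape for s in slices}
        if len(shapes) > 1:
            raise ValueError(f"slice shapes differ within {path}: {shapes}")
        arr = np.stack(slices, axis=0)
    else:
        if not path.exists():
            raise FileNotFoundError(str(path))
        arr = np.asarray(tifffile.imread(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a grayscale stack, got shape {arr.shape}")
    return arr


def _normalize(arr: np.ndarray, mode: str) -> np.ndarray:
    """Min-max normalize to [0, 1]; a degenerate range maps to all zeros."""
    arr = arr.astype(np.float32)

    def mm(a):
        lo, hi = float(a.min()), float(a.max())
        if hi <= lo:
            logger.warning(
                "degenerate intensity range (min == max == %g); mapping to 0", lo
            )
            return np.zeros_like(a)
        return (a - lo) / (hi - lo)

    if mode == "volume":
        return mm(arr)
    if mode == "slice":
        return np.stack([mm(s) for s in arr], axis=0)
    raise ValueError(f"unknown normalization mode {mode!r}")


def read_volume(
    image_path,
    label_paths: dict[str, str | Path] | None = None,
    labeled_slices=None,
    normalize: str = "volume",
    voxel_size_nm=None,
) -> AnnotatedVolume:
    """Assemble an :class:`AnnotatedVolume` from stacks on disk.

    Intensities are min-max normalized to [0, 1] (per volume by default, per
    slice with ``normalize='slice'``); labels are binarized at > 0. All stacks
    must share the same (Z, Y, X) shape. ``labeled_slices`` may be a sequence
    of z indices or a YAML sidecar path; by default every slice with a label
    stack is trusted.
    """
    intensities = _normalize(read_stack(image_path), normalize)
    labels: dict[str, np.ndarray] = {}
    for name, p in (label_paths or {}).items():
        lab = read_stack(p)
        if lab.shape != intensities.shape:
            raise ValueError(
                f"label stack '{name}' has shape {lab.shape}, "
                f"image stack has shape {intensities.shape}"
            )
        labels[name] = (lab > 0).astype(np.uint8)
    if labeled_slices is None:
        labeled_slices = range(intensities.shape[0]) if labels else []
    elif isinstance(labeled_slices, (str, Path)):
        labeled_slices = load_labeled_slices(labeled_slices)
    return AnnotatedVolume(
        intensities=intensities,
        labels=labels,
        labeled_slices=list(labeled_slices),
        voxel_size_nm=voxel_size_nm,
    )


def write_prediction(volume_labels: np.ndarray, path) -> Path:
    """Write a binary stack as a 0/255 multi-page TIFF, slice order preserved."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lab = np.asarray(volume_labels)
    if lab.ndim == 2:
        lab = lab[None]
    out = ((lab > 0).astype(np.uint8)) * 255
    tifffile.imwrite(path, out, photometric="minisblack")
    return path


def write_intensities(intensities: np.ndarray, path) -> Path:
    """Write a [0, 1] float stack as an 8-bit multi-page TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.clip(np.asarray(intensities, dtype=np.float32), 0.0, 1.0)
    tifffile.imwrite(
        path, np.round(arr * 255).astype(np.uint8), photometric="minisblack"
    )
    return path


def load_labeled_slices(path) -> list[int]:
    """Read the trusted-slice list from a YAML sidecar."""
    with open(path) as fh:
        meta = yaml.safe_load(fh)
    if isinstance(meta, dict):
        meta = meta["labeled_slices"]
    return [int(z) for z in meta]
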