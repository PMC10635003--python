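"""Synthetic vEM-like volumes with analytic ground truth.

Real FIB-SEM stacks of tumour biopsies are large and access-restricted, so the
rest of the pipeline is developed and tested against generated volumes that
copy the geometry the method assumes: a noisy granular background, a handful
of large textured nuclei, and small sparse nucleoli strictly contained inside
nuclei (the nucleolus class occupies well under 2% of the voxels, which is the
class-imbalance regime that motivates foreground-guaranteed sampling).

Shapes are axis-aligned ellipsoids with per-axis radii; a voxel belongs to a
structure iff its *center* lies inside the ellipsoid, so ground-truth voxel
counts can be checked by brute-force enumeration. Texture inside nuclei is
Gaussian-smoothed white noise; everything is reproducible from ``spec.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .volume_io import AnnotatedVolume, write_prediction, write_intensities

__all__ = [
    "SynthSpec",
    "generate_volume",
    "default_spec",
    "heterogeneous_spec",
    "save_synthetic",
]

_PLACEMENT_RETRIES = 200  # per nucleus; exceeding it means the volume is too crowded


@dataclass
class SynthSpec:
    """Parameters of one synthetic annotated volume.

    ``intensity_levels`` are the (background, nucleus, nucleolus) mean gray
    values in [0, 1]; they must be pairwise at least ``2 * noise_sd`` apart so
    the structures are learnable from intensity alone. The jitter fields add
    per-object offsets around those means; the "heterogeneous" preset uses a
    nucleolus jitter wide enough that some nucleoli overlap the nucleus level,
    which makes them genuinely hard to segment.
    """

    shape: tuple[int, int, int] = (64, 192, 192)
    n_nuclei: int = 6
    nucleolus_per_nucleus: tuple[int, int] = (1, 3)
    nucleus_radius_range: tuple[float, float] = (16.0, 26.0)
    nucleolus_radius_range: tuple[float, float] = (3.0, 6.0)
    intensity_levels: tuple[float, float, float] = (0.25, 0.60, 0.85)
    noise_sd: float = 0.05
    texture_scale: float = 4.0
    seed: int = 0
    nucleus_intensity_jitter: float = 0.0
    nucleolus_intensity_jitter: float = 0.0
    # z radii drawn from a separate range when set (flattened ellipsoids, so
    # that individual nuclei can fall entirely between two labeled slices)
    nucleus_z_radius_range: tuple[float, float] | None = None
    # each nucleus draws its own texture amplitude and correlation length,
    # giving every instance a recognizable signature that does not transfer
    # to instances never seen during training
    per_nucleus_texture: bool = False
    # allow nuclei to be cut by the first/last slice (centers placed down to
    # half a z-radius from the volume ends), as cells are in a real stack
    z_clip: bool = False
    # optional deterministic placement (mainly for geometry tests)
    nucleus_centers: list[tuple[float, float, float]] | None = None

    def validate(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"invalid shape {self.shape}")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        lo, hi = self.nucleolus_per_nucleus
        if not (0 <= lo <= hi):
            raise ValueError("invalid nucleolus_per_nucleus range")
        nlo, nhi = self.nucleus_radius_range
        slo, shi = self.nucleolus_radius_range
        zlo, zhi = self.nucleus_z_radius_range or self.nucleus_radius_range
        if not (0 < nlo <= nhi) or not (0 < slo <= shi) or not (0 < zlo <= zhi):
            raise ValueError("radius ranges must be positive and ordered")
        if shi >= min(nlo, zlo):
            raise ValueError(
                "nucleolus radii must be strictly smaller than nucleus radii"
            )
        if self.n_nuclei > 0 and (
            2 * zhi > self.shape[0] or any(2 * nhi > s for s in self.shape[1:])
        ):
            raise ValueError(
                f"nucleus radii ({zhi}, {nhi}) cannot fit inside shape {self.shape}"
            )
        bg, nuc, ncl = self.intensity_levels
        if not all(0.0 <= v <= 1.0 for v in (bg, nuc, ncl)):
            raise ValueError("intensity levels must lie in [0, 1]")
        gaps = (abs(nuc - bg), abs(ncl - bg), abs(ncl - nuc))
        if min(gaps) < 2 * self.noise_sd:
            raise ValueError(
                "intensity means must differ by at least 2 * noise_sd"
            )


def default_spec(seed: int = 0, shape: tuple[int, int, int] = (64, 192, 192)) -> SynthSpec:
    """Well-separated intensity levels; the easy reference condition."""
    return SynthSpec(shape=tuple(int(s) for s in shape), seed=seed)


def heterogeneous_spec(seed: int = 0, shape: tuple[int, int, int] = (64, 192, 192)) -> SynthSpec:
    """The hard, heterogeneous condition.

    Nuclei are flattened along z with per-nucleus gray levels, so a volume
    contains structures whose appearance never intersects the sparse labeled
    slices (dim, "unseen" nuclei), and nucleolus gray values are jittered down
    to overlap the nucleus level. Under this preset purely supervised training
    on a handful of slices visibly over-fits: per-slice Dice peaks at the
    labeled slices and dips in between.
    """
    return SynthSpec(
        shape=tuple(int(s) for s in shape),
        n_nuclei=12,
        nucleus_radius_range=(14.0, 24.0),
        nucleus_z_radius_range=(4.0, 10.0),
        nucleolus_radius_range=(2.5, 3.5),
        intensity_levels=(0.32, 0.50, 0.68),
        noise_sd=0.06,
        texture_scale=3.0,
        seed=seed,
        nucleus_intensity_jitter=0.16,
        nucleolus_intensity_jitter=0.18,
        per_nucleus_texture=True,
        z_clip=True,
    )


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    """Binary mask of voxels whose centers lie inside the ellipsoid."""
    zz, yy, xx = [np.arange(s, dtype=np.float64) for s in shape]
    dz = ((zz - center[0]) / radii[0]) ** 2
    dy = ((yy - center[1]) / radii[1]) ** 2
    dx = ((xx - center[2]) / radii[2]) ** 2
    return (
        dz[:, None, None] + dy[None, :, None] + dx[None, None, :]
    ) <= 1.0


def generate_volume(spec: SynthSpec) -> AnnotatedVolume:
    """Render one annotated volume; identical seeds give identical output.

    Raises ``RuntimeError`` if the requested nuclei cannot be placed without
    mutual overlap within the retry budget.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    Z, Y, X = spec.shape
    bg_level, nucleus_level, nucleolus_level = spec.intensity_levels

    # --- place nuclei -------------------------------------------------------
    centers: list[np.ndarray] = []
    radii: list[np.ndarray] = []
    zr_range = spec.nucleus_z_radius_range or spec.nucleus_radius_range
    for k in range(spec.n_nuclei):
        placed = False
        for _ in range(_PLACEMENT_RETRIES):
            r = rng.uniform(*spec.nucleus_radius_range, size=3)
            r[0] = rng.uniform(*zr_range)
            if spec.nucleus_centers is not None:
                c = np.asarray(spec.nucleus_centers[k], dtype=np.float64)
            else:
                zlo_c = 0.5 * r[0] if spec.z_clip else r[0]
                c = np.array(
                    [rng.uniform(zlo_c, spec.shape[0] - zlo_c)]
                    + [
                        rng.uniform(r[i], spec.shape[i] - r[i])
                        for i in (1, 2)
                    ]
                )
            # bounding boxes must not intersect (axis-aligned ellipsoids)
            ok = all(
                np.any(np.abs(c - cj) >= 0.8 * (r + rj))
                for cj, rj in zip(centers, radii)
            )
            if ok:
                centers.append(c)
                radii.append(r)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place nucleus {k + 1}/{spec.n_nuclei} in shape "
                f"{spec.shape} within {_PLACEMENT_RETRIES} retries"
            )

    nuclei = np.zeros(spec.shape, dtype=bool)
    base = np.full(spec.shape, bg_level, dtype=np.float32)
    nucleus_masks = []
    for c, r in zip(centers, radii):
        m = _ellipsoid_mask(spec.shape, c, r)
        nucleus_masks.append(m)
        nuclei |= m
        level = nucleus_level
        if spec.nucleus_intensity_jitter > 0:
            level = level + rng.uniform(
                -spec.nucleus_intensity_jitter, spec.nucleus_intensity_jitter
            )
        base[m] = level

    # --- nucleoli, strictly inside their nucleus ----------------------------
    nucleoli = np.zeros(spec.shape, dtype=bool)
    lo, hi = spec.nucleolus_per_nucleus
    for c, r, m in zip(centers, radii, nucleus_masks):
        for _ in range(int(rng.integers(lo, hi + 1))):
            sr = rng.uniform(*spec.nucleolus_radius_range, size=3)
            # normalized offset of norm <= 0.5 keeps the nucleolus well inside
            u = rng.normal(size=3)
            u *= rng.uniform(0, 0.5) / max(np.linalg.norm(u), 1e-9)
            sc = c + u * (r - sr)
            sm = _ellipsoid_mask(spec.shape, sc, sr) & m
            nucleoli |= sm
            level = nucleolus_level
            if spec.nucleolus_intensity_jitter > 0:
                level = level + rng.uniform(
                    -spec.nucleolus_intensity_jitter, 0.0
                )  # jitter downward, toward/overlapping the nucleus level
            base[sm] = level

    # --- texture inside nuclei + global shot noise --------------------------
    if nuclei.any() and spec.texture_scale > 0:
        if spec.per_nucleus_texture:
            for c, r, m in zip(centers, radii, nucleus_masks):
                amp = rng.uniform(0.5, 2.0) * spec.noise_sd
                scale = rng.uniform(0.6, 1.6) * spec.texture_scale
                pad = int(np.ceil(3 * scale))
                lo = np.maximum(np.floor(c - r).astype(int) - pad, 0)
                hi = np.minimum(
                    np.ceil(c + r).astype(int) + 1 + pad, spec.shape
                ).astype(int)
                box = tuple(slice(a, b) for a, b in zip(lo, hi))
                tex = gaussian_filter(
                    rng.normal(size=tuple(hi - lo)).astype(np.float32), scale
                )
                tex /= max(float(tex.std()), 1e-9)
                mbox = m[box]
                base[box][mbox] += amp * tex[mbox]
        else:
            tex = gaussian_filter(
                rng.normal(size=spec.shape).astype(np.float32), spec.texture_scale
            )
            tex /= max(float(tex.std()), 1e-9)
            base[nuclei] += spec.noise_sd * tex[nuclei]
    vol = base + rng.normal(0.0, spec.noise_sd, size=spec.shape).astype(
        np.float32
    )
    vol = np.clip(vol, 0.0, 1.0).astype(np.float32)

    labels = {
        "nuclei": nuclei.astype(np.uint8),
        "nucleoli": (nucleoli & nuclei).astype(np.uint8),
    }
    return AnnotatedVolume(
        intensities=vol,
        labels=labels,
        labeled_slices=list(range(Z)),
    )


def save_synthetic(volume: AnnotatedVolume, spec: SynthSpec, outdir) -> dict[str, Path]:
    """Write intensities (8-bit multi-page TIFF), one 0/255 label stack per
    structure, and a YAML sidecar recording the generating spec and seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    img_path = outdir / "image.tif"
    write_intensities(volume.intensities, img_path)
    paths["image"] = img_path
    for name, lab in volume.labels.items():
        p = outdir / f"labels_{name}.tif"
        write_prediction(lab, p)
        paths[name] = p
    meta = dataclasses.asdict(spec)
    meta["labeled_slices"] = [int(z) for z in volume.labeled_slices]
    meta_path = outdir / "meta.yaml"
    with open(meta_path, "w") as fh:
        yaml.safe_dump(_yamlable(meta), fh, sort_keys=False)
    paths["meta"] = meta_path
    return paths


def _yamlable(obj):
    if isinstance(obj, dict):
        return {k: _yamlable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yamlable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
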