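"""Validated run configuration, experiment manifest, and the experiment grid.

A run is described by one YAML file (every CLI flag mirrors a key here).
Validation is strict: unknown keys and out-of-range values are rejected with
the offending key named. ``run_experiment`` executes the requested
(structure, n_train, mode) grid sequentially and deterministically, writing a
checkpoint, a predicted stack and a Dice report per cell plus a grid summary
CSV suitable for model ranking; failures in one cell are recorded in the
manifest and do not stop the others.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .losses import WarmupSchedule
from .metrics import evaluate_volume
from .models import ModelConfig, save_checkpoint
from .sampling import SamplerConfig, select_labeled_slices
from .synthdata import default_spec, generate_volume, heterogeneous_spec
from .trainer import (
    CPSTrainConfig,
    TrainConfig,
    predict_volume,
    train_cps,
    train_supervised,
)
from .volume_io import AnnotatedVolume, read_volume, write_prediction

logger = logging.getLogger("vemseg")

__all__ = [
    "RunConfig",
    "load_config",
    "dump_config",
    "RunManifest",
    "run_experiment",
    "setup_logging",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class VolumeSection(_Strict):
    source: Literal["synthetic", "files"] = "synthetic"
    preset: Literal["default", "heterogeneous"] = "heterogeneous"
    shape: tuple[int, int, int] = (64, 192, 192)
    seed: int = 7
    image: str | None = None
    labels: dict[str, str] = Field(default_factory=dict)
    labeled_slices: str | None = None
    normalize: Literal["volume", "slice"] = "volume"


class SamplerSection(_Strict):
    context_size: int = Field(96, ge=1)
    out_size: int = Field(48, ge=1)
    foreground_fraction: float = Field(0.99, ge=0.0, le=1.0)
    augment: bool = True
    slice_spacing: Literal["centered", "endpoint"] = "centered"


class ModelSection(_Strict):
    arch: Literal["resunet", "unetpp"] = "resunet"
    base_width: int = Field(8, ge=1)
    depth: int = Field(3, ge=2)
    deep_supervision: bool = True


class TrainSection(_Strict):
    steps: int = Field(1000, ge=0)
    batch_size: int = Field(2, ge=1)
    batch_size_cps: int = Field(2, ge=1)
    lr: float = Field(1e-3, gt=0)
    seed: int = 0
    lambda_max: float = Field(1.0, ge=0.0)
    warmup_steps: int = Field(400, ge=0)
    cutmix: bool = True
    cps_foreground_fraction: float = Field(0.5, ge=0.0, le=1.0)
    dice_eps: float = Field(1.0, ge=0.0)


class GridSection(_Strict):
    structures: list[str] = Field(default_factory=lambda: ["nuclei"])
    n_train: list[int] = Field(default_factory=lambda: [7])
    modes: list[Literal["supervised", "cps"]] = Field(
        default_factory=lambda: ["supervised", "cps"]
    )


class RunConfig(_Strict):
    output_dir: str = "runs/run"
    volume: VolumeSection = Field(default_factory=VolumeSection)
    sampler: SamplerSection = Field(default_factory=SamplerSection)
    model: ModelSection = Field(default_factory=ModelSection)
    train: TrainSection = Field(default_factory=TrainSection)
    grid: GridSection = Field(default_factory=GridSection)

    # -- converters to the library dataclasses --------------------------------

    def to_sampler_config(self, rng_seed: int = 0) -> SamplerConfig:
        s = SamplerConfig(
            context_size=self.sampler.context_size,
            out_size=self.sampler.out_size,
            foreground_fraction=self.sampler.foreground_fraction,
            augment=self.sampler.augment,
            rng_seed=rng_seed,
            slice_spacing=self.sampler.slice_spacing,
        )
        s.validate()
        return s

    def to_model_config(self) -> ModelConfig:
        m = ModelConfig(
            arch=self.model.arch,
            base_width=self.model.base_width,
            depth=self.model.depth,
            deep_supervision=self.model.deep_supervision,
        )
        m.validate()
        return m

    def to_train_config(self, seed: int | None = None) -> TrainConfig:
        return TrainConfig(
            steps=self.train.steps,
            batch_size=self.train.batch_size,
            lr=self.train.lr,
            seed=self.train.seed if seed is None else seed,
            sampler=self.to_sampler_config(),
            dice_eps=self.train.dice_eps,
        )

    def to_cps_config(self, seed: int | None = None) -> CPSTrainConfig:
        return CPSTrainConfig(
            steps=self.train.steps,
            batch_size_labeled=self.train.batch_size,
            batch_size_cps=self.train.batch_size_cps,
            schedule=WarmupSchedule(self.train.lambda_max, self.train.warmup_steps),
            cutmix=self.train.cutmix,
            cps_foreground_fraction=self.train.cps_foreground_fraction,
            lr=self.train.lr,
            seed=self.train.seed if seed is None else seed,
            sampler=self.to_sampler_config(),
            dice_eps=self.train.dice_eps,
        )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; raises with the offending
    key named on unknown keys, type mismatches or constraint violations."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ValueError(f"invalid config {path}: {exc}") from exc


def dump_config(cfg: RunConfig) -> dict:
    return json.loads(cfg.model_dump_json())


def setup_logging(level=logging.INFO):
    h = logging.StreamHandler()
    h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("vemseg")
    if not root.handlers:
        root.addHandler(h)
    root.setLevel(level)


class RunManifest:
    """Record of one experiment run, written before training starts and
    finalized afterwards; sufficient to re-run the experiment."""

    def __init__(self, config: RunConfig, out_dir: Path):
        self.path = Path(out_dir) / "manifest.json"
        self.data = {
            "package_version": __version__,
            "config": dump_config(config),
            "started_at": _now(),
            "finished_at": None,
            "input_digests": {},
            "outputs": [],
            "failures": [],
        }

    def add_digest(self, name: str, path_or_desc):
        p = Path(str(path_or_desc))
        if p.exists() and p.is_file():
            self.data["input_digests"][name] = hashlib.sha256(
                p.read_bytes()
            ).hexdigest()
        else:
            self.data["input_digests"][name] = str(path_or_desc)

    def add_output(self, cell: str, kind: str, path):
        self.data["outputs"].append(
            {"cell": cell, "kind": kind, "path": str(path)}
        )

    def add_failure(self, cell: str, error: str):
        self.data["failures"].append({"cell": cell, "error": error})

    def write(self):
        self.path.parent.mkdir(parents=True, exist_ok=True)
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=2)

    def finalize(self):
        self.data["finished_at"] = _now()
        self.write()


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()


def _load_volume(cfg: RunConfig) -> AnnotatedVolume:
    v = cfg.volume
    if v.source == "synthetic":
        spec = (
            heterogeneous_spec(seed=v.seed, shape=v.shape)
            if v.preset == "heterogeneous"
            else default_spec(seed=v.seed, shape=v.shape)
        )
        return generate_volume(spec)
    if not v.image:
        raise ValueError("volume.source == 'files' requires volume.image")
    return read_volume(
        v.image, v.labels, labeled_slices=v.labeled_slices, normalize=v.normalize
    )


def run_experiment(cfg: RunConfig, out_dir=None) -> Path:
    """Execute the configured grid; returns the manifest path.

    Each grid cell produces: a checkpoint, a predicted 0/255 stack, a Dice
    report (JSON + per-slice CSV). A ``summary.csv`` over all cells holds one
    row per (mode, structure, n_train) with 3D/average Dice and the
    training-slice vs held-out per-slice means.
    """
    out = Path(out_dir if out_dir is not None else cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(cfg, out)
    if cfg.volume.source == "files":
        manifest.add_digest("image", cfg.volume.image)
        for name, p in cfg.volume.labels.items():
            manifest.add_digest(f"labels_{name}", p)
    else:
        manifest.add_digest(
            "volume", f"synthetic:{cfg.volume.preset}:seed={cfg.volume.seed}"
        )
    manifest.write()

    volume = _load_volume(cfg)
    rows = []
    for structure in cfg.grid.structures:
        if structure not in volume.labels:
            manifest.add_failure(structure, f"no labels for {structure!r}")
            continue
        for n_train in cfg.grid.n_train:
            sel = select_labeled_slices(
                n_train, volume.n_slices, cfg.sampler.slice_spacing
            )
            train_vol = volume.with_labeled_slices(sel)
            for mode in cfg.grid.modes:
                cell = f"{mode}-{cfg.model.arch}-{structure}-n{n_train}"
                cell_dir = out / cell
                try:
                    logger.info("running cell %s", cell)
                    if mode == "supervised":
                        net, _log = train_supervised(
                            train_vol, structure, cfg.to_model_config(), cfg.to_train_config()
                        )
                    else:
                        net, _net2, _log = train_cps(
                            train_vol, structure, cfg.to_cps_config(), cfg.to_model_config()
                        )
                    ckpt = save_checkpoint(
                        cell_dir / "checkpoint", net, step=cfg.train.steps,
                        seed=cfg.train.seed,
                    )
                    manifest.add_output(cell, "checkpoint", ckpt)
                    pred, _conf = predict_volume(net, volume, cfg.to_sampler_config())
                    ppath = write_prediction(pred, cell_dir / "prediction.tif")
                    manifest.add_output(cell, "prediction", ppath)
                    report = evaluate_volume(pred, volume.labels[structure])
                    jp, cp = report.save(cell_dir / "dice")
                    manifest.add_output(cell, "report", jp)
                    manifest.add_output(cell, "per_slice", cp)
                    heldout = [
                        z for z in range(volume.n_slices) if z not in set(sel)
                    ]
                    rows.append(
                        {
                            "mode": mode,
                            "arch": cfg.model.arch,
                            "structure": structure,
                            "n_train": n_train,
                            "dice3d": report.dice3d,
                            "average_dice": report.average_dice,
                            "train_slice_dice": report.mean_over(sel),
                            "heldout_dice": report.mean_over(heldout),
                        }
                    )
                except Exception as exc:  # cell isolation: record and continue
                    logger.exception("cell %s failed", cell)
                    manifest.add_failure(cell, f"{type(exc).__name__}: {exc}")
    if rows:
        summary = pd.DataFrame(rows)
        summary.to_csv(out / "summary.csv", index=False)
        manifest.add_output("grid", "summary", out / "summary.csv")
    manifest.finalize()
    return manifest.path
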