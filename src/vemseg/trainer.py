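"""Training orchestration and whole-volume inference.

Supervised training minimizes the per-crop soft Dice loss on crops drawn from
the trusted slices only. Semi-supervised (CPS) training runs two networks
that differ only by initialization seed: each step combines the supervised
loss of both networks on labeled crops with the cross-pseudo-supervision loss
on a mixed labeled+unlabeled crop batch, weighted by the warm-up schedule.
With CutMix enabled the CPS crops are mixed pairwise (item i with item
B-1-i) and the pseudo-label targets are assembled from the *unmixed* crops.

Inference tiles each slice on an overlapping grid at the training context
scale, averages confidences in the overlaps, upsamples to native resolution
and takes the per-pixel argmax (ties go to background).
"""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .autograd import Adam, BatchNorm2d, Tensor, no_grad
from .losses import (
    DEFAULT_DICE_EPS,
    WarmupSchedule,
    batch_soft_dice_loss,
    cps_loss_from_pseudo,
    lambda_at,
    mix_with_mask,
    pseudo_label,
    sample_cutmix_box,
)
from .models import (
    ModelConfig,
    SegmentationNet,
    build_model,
    deep_supervision_loss,
)
from .sampling import SamplerConfig, dihedral, sample_crops, sample_training_batch
from .volume_io import AnnotatedVolume

logger = logging.getLogger("vemseg")

__all__ = [
    "TrainConfig",
    "CPSTrainConfig",
    "TrainState",
    "train_supervised",
    "train_cps",
    "run_steps",
    "init_supervised_state",
    "init_cps_state",
    "save_train_state",
    "load_train_state",
    "predict_volume",
    "SymmetrizedNet",
]

_PSEUDO_FG_ROUNDS = 3  # re-draw rounds for the pseudo-label foreground check


@dataclass
class TrainConfig:
    """Fully-supervised training settings."""

    steps: int = 300
    batch_size: int = 4
    lr: float = 1e-3
    seed: int = 0
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    dice_eps: float = DEFAULT_DICE_EPS


@dataclass
class CPSTrainConfig:
    """Cross-pseudo-supervision training settings.

    ``cps_foreground_fraction`` is the required fraction of CPS-batch crops
    containing foreground; on labeled crops it is enforced with the true
    labels, on unlabeled crops (after warm-up) with the first network's
    current pseudo-labels. The two networks are initialized from ``seed`` and
    ``seed + 1``.
    """

    steps: int = 300
    batch_size_labeled: int = 4
    batch_size_cps: int = 4
    schedule: WarmupSchedule = field(default_factory=lambda: WarmupSchedule(1.0, 100))
    cutmix: bool = True
    cps_foreground_fraction: float = 0.5
    lr: float = 1e-3
    seed: int = 0
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    dice_eps: float = DEFAULT_DICE_EPS


@dataclass
class TrainState:
    """Everything needed to continue a run: networks, optimizers, data RNG
    streams, step counter and the loss log."""

    mode: str  # "supervised" | "cps"
    step: int
    nets: list[SegmentationNet]
    opts: list[Adam]
    data_rngs: list[np.random.Generator]
    cps_rng: np.random.Generator | None
    config: TrainConfig | CPSTrainConfig
    log: list[dict] = field(default_factory=list)


def _data_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), 101])


def init_supervised_state(model_cfg: ModelConfig, cfg: TrainConfig) -> TrainState:
    net = build_model(model_cfg, seed=cfg.seed)
    return TrainState(
        mode="supervised",
        step=0,
        nets=[net],
        opts=[Adam(net.parameters(), lr=cfg.lr)],
        data_rngs=[_data_rng(cfg.seed)],
        cps_rng=None,
        config=cfg,
    )


def init_cps_state(model_cfg: ModelConfig, cfg: CPSTrainConfig) -> TrainState:
    nets = [build_model(model_cfg, seed=cfg.seed + k) for k in (0, 1)]
    return TrainState(
        mode="cps",
        step=0,
        nets=nets,
        opts=[Adam(n.parameters(), lr=cfg.lr) for n in nets],
        data_rngs=[_data_rng(cfg.seed + k) for k in (0, 1)],
        cps_rng=np.random.default_rng([int(cfg.seed), 202]),
        config=cfg,
    )


def _supervised_loss(net: SegmentationNet, images, labels, eps: float):
    branches = net.branch_confidences(Tensor(images))
    if len(branches) == 1:
        return batch_soft_dice_loss(labels, branches[0][:, 1], eps)
    return deep_supervision_loss(branches, labels, eps)


def _labeled_loss(state: TrainState, k: int, volume, structure, batch_size: int):
    """Supervised Dice loss of network ``k`` on a fresh labeled batch drawn
    from that network's own RNG stream (graph kept for a later backward)."""
    cfg = state.config
    batch = sample_training_batch(
        volume, structure, batch_size, cfg.sampler, rng=state.data_rngs[k]
    )
    return _supervised_loss(state.nets[k], batch.images, batch.labels, cfg.dice_eps)


def _supervised_step(
    state: TrainState, k: int, volume, structure, batch_size: int
) -> float:
    loss = _labeled_loss(state, k, volume, structure, batch_size)
    state.opts[k].zero_grad()
    loss.backward()
    state.opts[k].step()
    return loss.item()


@contextmanager
def _frozen_bn_stats(*nets):
    """Keep batch-stat normalization but stop running-average updates, so
    auxiliary forwards (mixed or unlabeled crops) do not shift the statistics
    used at evaluation."""
    bns = [m for net in nets for m in net.modules() if isinstance(m, BatchNorm2d)]
    for m in bns:
        m.update_stats = False
    try:
        yield
    finally:
        for m in bns:
            m.update_stats = True


def _pseudo_labels(net: SegmentationNet, images: np.ndarray) -> np.ndarray:
    """Hard pseudo-label maps for a crop batch, computed with the network's
    deployment semantics (evaluation mode: running batch-norm statistics), so
    pseudo-labels are stable against small-batch statistic noise."""
    was_training = net.training
    net.eval()
    try:
        with no_grad():
            conf = net.confidences(Tensor(images))
    finally:
        if was_training:
            net.train()
    return pseudo_label(conf)


def _fg_flags(pl: np.ndarray) -> np.ndarray:
    """Per-item flag: does a pseudo-label map contain foreground?"""
    return (pl == 1).reshape(len(pl), -1).any(axis=1)


def _cps_images(
    state: TrainState, volume, structure, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the CPS crop batch from labeled + unlabeled slices.

    Crops are drawn from the whole stack (which is overwhelmingly unlabeled
    under sparse annotation). The foreground-content guarantee — at least
    ``cps_foreground_fraction`` of the batch containing the structure — is
    enforced with the first network's current pseudo-labels once the warm-up
    has finished; during warm-up, when pseudo-labels are still unreliable,
    the guaranteed share is drawn from labeled slices using the true labels.

    Returns the batch together with network 1's pseudo-label maps for it
    (already needed for the foreground check; reused for the CPS loss).
    """
    cfg = state.config
    rng = state.cps_rng
    net1 = state.nets[0]
    B = cfg.batch_size_cps
    all_slices = list(range(volume.n_slices))
    warmed_up = lam >= cfg.schedule.lambda_max
    if not warmed_up and cfg.cps_foreground_fraction > 0:
        quota = min(B, int(np.ceil(cfg.cps_foreground_fraction * B)))
        parts = []
        if quota:
            parts.append(
                sample_crops(
                    volume.intensities,
                    volume.labels[structure],
                    volume.labeled_slices,
                    quota,
                    cfg.sampler,
                    rng,
                    foreground_fraction=1.0,
                ).images
            )
        if B - quota:
            parts.append(
                sample_crops(
                    volume.intensities, None, all_slices, B - quota, cfg.sampler, rng
                ).images
            )
        x = np.concatenate(parts, axis=0)
        return x, _pseudo_labels(net1, x)

    x = sample_crops(
        volume.intensities, None, all_slices, B, cfg.sampler, rng
    ).images
    pl1 = _pseudo_labels(net1, x)
    if cfg.cps_foreground_fraction > 0:
        need = int(np.ceil(cfg.cps_foreground_fraction * B))
        short = 0
        for _ in range(_PSEUDO_FG_ROUNDS):
            short = need - int(_fg_flags(pl1).sum())
            if short <= 0:
                break
            missing = np.flatnonzero(~_fg_flags(pl1))[:short]
            x[missing] = sample_crops(
                volume.intensities, None, all_slices, len(missing), cfg.sampler, rng
            ).images
            pl1[missing] = _pseudo_labels(net1, x[missing])
        if short > 0:
            # rejection failed (very sparse structure): fall back to crops
            # centered on true foreground from the labeled slices
            missing = np.flatnonzero(~_fg_flags(pl1))[:short]
            if len(missing):
                x[missing] = sample_crops(
                    volume.intensities,
                    volume.labels[structure],
                    volume.labeled_slices,
                    len(missing),
                    cfg.sampler,
                    rng,
                    foreground_fraction=1.0,
                ).images
                pl1[missing] = _pseudo_labels(net1, x[missing])
    return x, pl1


def _cps_step(state: TrainState, volume, structure) -> dict:
    """One CPS step: a single optimizer update per network on the combined
    objective  supervised Dice loss + lambda(step) * CPS loss."""
    cfg = state.config
    lam = lambda_at(state.step, cfg.schedule)
    state.opts[0].zero_grad()
    state.opts[1].zero_grad()
    sup_vals = []
    for k in (0, 1):
        loss = _labeled_loss(state, k, volume, structure, cfg.batch_size_labeled)
        loss.backward()  # gradients accumulate; the optimizer steps once below
        sup_vals.append(loss.item())
    cps = None
    if lam > 0.0:
        x, pl1 = _cps_images(state, volume, structure, lam)
        net1, net2 = state.nets
        pl2 = _pseudo_labels(net2, x)
        if cfg.cutmix:
            boxes = [
                sample_cutmix_box(cfg.sampler.out_size, state.cps_rng)
                for _ in range(len(x))
            ]
            from .losses import cutmix_apply

            xm, mask = cutmix_apply(x, x[::-1], boxes)
            # eval-mode pseudo-labels are per-sample, so the reversed batch's
            # pseudo-labels are just the reversed pseudo-labels
            pl1 = mix_with_mask(pl1, pl1[::-1], mask)
            pl2 = mix_with_mask(pl2, pl2[::-1], mask)
            x_in = xm
        else:
            x_in = x
        with _frozen_bn_stats(net1, net2):
            conf1 = net1.confidences(Tensor(x_in))
            conf2 = net2.confidences(Tensor(x_in))
        cps = cps_loss_from_pseudo(conf1, conf2, pl1, pl2, cfg.dice_eps)
        (cps * lam).backward()
    state.opts[0].step()
    state.opts[1].step()
    return {
        "step": state.step,
        "sup1": sup_vals[0],
        "sup2": sup_vals[1],
        "cps": 0.0 if cps is None else cps.item(),
        "lambda": lam,
    }


def run_steps(state: TrainState, volume: AnnotatedVolume, structure: str, n_steps: int) -> TrainState:
    """Advance a training state by ``n_steps`` (works for either mode)."""
    if structure not in volume.labels:
        raise KeyError(f"volume has no labels for structure {structure!r}")
    for _ in range(n_steps):
        if state.mode == "supervised":
            loss = _supervised_step(
                state, 0, volume, structure, state.config.batch_size
            )
            entry = {"step": state.step, "loss": loss}
        else:
            entry = _cps_step(state, volume, structure)
        state.log.append(entry)
        state.step += 1
        if state.step % 100 == 0 or state.step == 1:
            logger.info("step %d: %s", state.step, entry)
    return state


def train_supervised(
    volume: AnnotatedVolume,
    structure: str,
    model_cfg: ModelConfig,
    cfg: TrainConfig,
) -> tuple[SegmentationNet, list[dict]]:
    """Train one network on the volume's trusted slices; with ``steps == 0``
    the returned weights equal the initialization."""
    if not volume.labeled_slices:
        raise ValueError("volume has no labeled slices")
    state = init_supervised_state(model_cfg, cfg)
    run_steps(state, volume, structure, cfg.steps)
    return state.nets[0], state.log


def train_cps(
    volume: AnnotatedVolume,
    structure: str,
    cfg: CPSTrainConfig,
    model_cfg: ModelConfig,
) -> tuple[SegmentationNet, SegmentationNet, list[dict]]:
    """Train a CPS pair. With ``schedule.lambda_max == 0`` each network's
    trajectory is identical to an independent supervised run seeded with
    ``cfg.seed`` and ``cfg.seed + 1`` respectively."""
    if not volume.labeled_slices:
        raise ValueError("volume has no labeled slices")
    state = init_cps_state(model_cfg, cfg)
    run_steps(state, volume, structure, cfg.steps)
    return state.nets[0], state.nets[1], state.log


# -- persistence -----------------------------------------------------------------


def save_train_state(path, state: TrainState) -> Path:
    """Persist a run so that save -> load -> continue matches an uninterrupted
    run at the logged-metric level."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload: dict[str, np.ndarray] = {}
    meta = {
        "mode": state.mode,
        "step": state.step,
        "n_nets": len(state.nets),
        "model_config": state.nets[0].config.__dict__,
        "config_class": type(state.config).__name__,
        "config": _jsonable(state.config),
        "log": state.log,
        "rng_states": [r.bit_generator.state for r in state.data_rngs],
        "cps_rng_state": None
        if state.cps_rng is None
        else state.cps_rng.bit_generator.state,
    }
    payload["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    for k, net in enumerate(state.nets):
        for key, arr in net.state_dict().items():
            payload[f"net{k}/{key}"] = arr
        opt = state.opts[k]
        payload[f"opt{k}/t"] = np.array(opt.t)
        for i, (m, v) in enumerate(zip(opt.m, opt.v)):
            payload[f"opt{k}/m{i}"] = m
            payload[f"opt{k}/v{i}"] = v
    if not str(path).endswith(".npz"):
        path = Path(str(path) + ".npz")
    np.savez(path, **payload)
    return path


def load_train_state(path) -> TrainState:
    path = Path(path)
    if not path.exists() and path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        model_cfg = ModelConfig(**meta["model_config"])
        cfg_dict = dict(meta["config"])
        sampler = SamplerConfig(**cfg_dict.pop("sampler"))
        if meta["config_class"] == "CPSTrainConfig":
            schedule = WarmupSchedule(**cfg_dict.pop("schedule"))
            cfg = CPSTrainConfig(sampler=sampler, schedule=schedule, **cfg_dict)
            state = init_cps_state(model_cfg, cfg)
        else:
            cfg = TrainConfig(sampler=sampler, **cfg_dict)
            state = init_supervised_state(model_cfg, cfg)
        state.step = int(meta["step"])
        state.log = list(meta["log"])
        for k, net in enumerate(state.nets):
            prefix = f"net{k}/"
            net.load_state_dict(
                {
                    key[len(prefix) :]: data[key]
                    for key in data.files
                    if key.startswith(prefix)
                }
            )
            opt = state.opts[k]
            opt.t = int(data[f"opt{k}/t"])
            opt.m = [
                np.array(data[f"opt{k}/m{i}"]) for i in range(len(opt.m))
            ]
            opt.v = [
                np.array(data[f"opt{k}/v{i}"]) for i in range(len(opt.v))
            ]
        for r, s in zip(state.data_rngs, meta["rng_states"]):
            r.bit_generator.state = s
        if state.cps_rng is not None and meta["cps_rng_state"] is not None:
            state.cps_rng.bit_generator.state = meta["cps_rng_state"]
    return state


def _jsonable(cfg) -> dict:
    out = {}
    for k, v in cfg.__dict__.items():
        if isinstance(v, (SamplerConfig, WarmupSchedule)):
            out[k] = dict(v.__dict__)
        else:
            out[k] = v
    return out


# -- inference --------------------------------------------------------------------


class SymmetrizedNet:
    """Test-time symmetrization wrapper: averages confidences over a set of
    dihedral transforms of the input (inverse-transformed back). Disabled by
    default in the pipeline; provided for symmetry checks and optional use."""

    def __init__(self, net: SegmentationNet, transforms=(0, 2)):
        self.net = net
        self.transforms = tuple(transforms)
        self.config = net.config

    def eval(self):
        self.net.eval()
        return self

    def train(self):
        self.net.train()
        return self

    def confidences(self, x: Tensor) -> Tensor:
        total = None
        for t in self.transforms:
            xt = Tensor(np.ascontiguousarray(dihedral(x.data, t)))
            ct = self.net.confidences(xt).data
            ct = _inverse_dihedral(ct, t)
            total = ct if total is None else total + ct
        return Tensor(np.ascontiguousarray(total / len(self.transforms)))


def _inverse_dihedral(arr: np.ndarray, t: int) -> np.ndarray:
    out = np.rot90(arr, k=-(t % 4), axes=(-2, -1))
    if t >= 4:
        out = np.flip(out, axis=-1)
    return out


def _grid_anchors(dim: int, context: int, stride: int) -> list[int]:
    last = max(dim - context, 0)
    xs = list(range(0, last + 1, stride))
    if xs[-1] != last:
        xs.append(last)
    return xs


def predict_volume(
    net,
    volume: AnnotatedVolume,
    sampler_cfg: SamplerConfig,
    tile_batch: int = 8,
    slices=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Slice-wise tiled inference.

    Tiles are taken on a fixed overlapping grid (stride = half a context
    window), forwarded in evaluation mode at the training downsampling factor,
    and the foreground confidences are averaged in the overlaps after nearest-
    neighbour upsampling to native resolution. Returns the binary prediction
    stack (argmax; tie -> background) and the blended confidence stack.
    """
    sampler_cfg.validate()
    from .sampling import extract_context_tile  # local to avoid cycle at import

    net.eval()
    Z, H, W = volume.intensities.shape
    cs, f, out = sampler_cfg.context_size, sampler_cfg.factor, sampler_cfg.out_size
    if H < cs or W < cs:
        logger.warning(
            "volume (%d, %d) smaller than one context tile (%d); padding", H, W, cs
        )
    stride = max(cs // 2, 1)
    zs = list(range(Z)) if slices is None else [int(z) for z in slices]
    tasks = [
        (z, y0, x0)
        for z in zs
        for y0 in _grid_anchors(H, cs, stride)
        for x0 in _grid_anchors(W, cs, stride)
    ]
    acc = np.zeros((Z, H, W), dtype=np.float32)
    wt = np.zeros((Z, H, W), dtype=np.float32)
    for start in range(0, len(tasks), tile_batch):
        chunk = tasks[start : start + tile_batch]
        tiles = np.stack(
            [
                extract_context_tile(volume.intensities[z], y0, x0, sampler_cfg)
                for z, y0, x0 in chunk
            ]
        )[:, None]
        with no_grad():
            conf = net.confidences(Tensor(tiles)).data[:, 1]  # (b, out, out)
        if f == 1:
            up = conf
        else:
            # bilinear upsampling of the confidences recovers sub-block
            # boundary precision lost to the context downsampling
            up = np.stack(
                [
                    resize(c, (cs, cs), order=1, preserve_range=True,
                           anti_aliasing=False)
                    for c in conf
                ]
            ).astype(np.float32)
        for (z, y0, x0), c in zip(chunk, up):
            he = min(y0 + cs, H) - y0
            we = min(x0 + cs, W) - x0
            acc[z, y0 : y0 + he, x0 : x0 + we] += c[:he, :we]
            wt[z, y0 : y0 + he, x0 : x0 + we] += 1.0
    conf = acc / np.maximum(wt, 1.0)
    pred = (conf > 0.5).astype(np.uint8)
    return pred, conf
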