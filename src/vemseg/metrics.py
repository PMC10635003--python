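"""Dice evaluation: 3-D Dice, per-slice average Dice, and model ranking.

Two conventions coexist for volumetric masks:

* ``3D Dice`` — Dice of the flattened volumes; it reflects the captured
  fraction of the target structure.
* ``average Dice`` — the mean of per-slice Dice scores; it up-weights slices
  with few foreground pixels (a slice with a single mislabeled pixel can score
  0 and drag the mean down regardless of its size).

Both are reported, along with the full per-slice profile, which makes the
over-fitting signature of sparsely-supervised models visible: performance
peaks at the training slices and dips in between.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "dice",
    "evaluate_volume",
    "DiceReport",
    "RankingSummary",
    "rank_models",
    "plot_per_slice",
]


def dice(pred: np.ndarray, gt: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two binary masks; two empty masks
    score 1 by convention (needed for background-only slices)."""
    pred, gt = np.asarray(pred), np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    p = pred > 0
    g = gt > 0
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


@dataclass
class DiceReport:
    """Evaluation of one predicted volume against ground truth."""

    dice3d: float
    average_dice: float
    per_slice: list[tuple[int, float]] = field(default_factory=list)

    def per_slice_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_slice, columns=["z", "dice"])

    def save(self, prefix) -> tuple[Path, Path]:
        """Write the summary as JSON and the per-slice profile as CSV."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        jpath = Path(f"{prefix}.json")
        with open(jpath, "w") as fh:
            json.dump(
                {"dice3d": self.dice3d, "average_dice": self.average_dice}, fh
            )
        cpath = Path(f"{prefix}_per_slice.csv")
        self.per_slice_frame().to_csv(cpath, index=False)
        return jpath, cpath

    def mean_over(self, slices) -> float:
        """Mean per-slice Dice over a subset of z indices."""
        wanted = set(int(z) for z in slices)
        vals = [d for z, d in self.per_slice if z in wanted]
        if not vals:
            raise ValueError("no per-slice scores for the requested slices")
        return float(np.mean(vals))


def evaluate_volume(pred_volume: np.ndarray, gt_volume: np.ndarray) -> DiceReport:
    """3-D Dice on the flattened volumes plus the per-slice profile, whose
    mean is the average Dice."""
    pred_volume, gt_volume = np.asarray(pred_volume), np.asarray(gt_volume)
    if pred_volume.shape != gt_volume.shape:
        raise ValueError(
            f"shape mismatch: pred {pred_volume.shape} vs gt {gt_volume.shape}"
        )
    per_slice = [
        (z, dice(pred_volume[z], gt_volume[z]))
        for z in range(pred_volume.shape[0])
    ]
    return DiceReport(
        dice3d=dice(pred_volume, gt_volume),
        average_dice=float(np.mean([d for _, d in per_slice])),
        per_slice=per_slice,
    )


@dataclass
class RankingSummary:
    """Per-model mean, standard deviation and average rank over a grid of
    evaluation settings (1 = best; ties share the mean of the tied ranks)."""

    table: pd.DataFrame  # index: model; columns: mean, std, average_rank

    def best(self) -> str:
        return str(self.table["average_rank"].idxmin())


def rank_models(score_table: pd.DataFrame, ddof: int = 0) -> RankingSummary:
    """Summarize a complete model × setting grid of Dice scores.

    ``score_table``: rows are models, columns are evaluation settings (e.g.
    (structure, volume, n_train) cells). Standard deviation uses the
    population formula by default (``ddof=0``). Ranks are computed per
    setting, descending in score, and averaged per model; any strictly
    monotone transform of all scores leaves them unchanged.
    """
    df = pd.DataFrame(score_table).astype(float)
    if df.isna().any().any():
        missing = df.columns[df.isna().any()].tolist()
        raise ValueError(f"score table has missing cells in settings {missing}")
    ranks = df.rank(axis=0, ascending=False, method="average")
    out = pd.DataFrame(
        {
            "mean": df.mean(axis=1),
            "std": df.std(axis=1, ddof=ddof),
            "average_rank": ranks.mean(axis=1),
        }
    )
    return RankingSummary(table=out)


def plot_per_slice(
    reports: dict[str, DiceReport],
    train_slices=(),
    path=None,
    title="Per-slice Dice",
):
    """Per-slice Dice profiles with the training slices marked by vertical
    lines; returns the matplotlib figure (saved to ``path`` when given)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    for name, rep in reports.items():
        zz = [z for z, _ in rep.per_slice]
        dd = [d for _, d in rep.per_slice]
        ax.plot(zz, dd, label=name, lw=1.2)
    for z in train_slices:
        ax.axvline(int(z), color="black", lw=0.8, alpha=0.7)
    ax.set_xlabel("slice (z)")
    ax.set_ylabel("Dice")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
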