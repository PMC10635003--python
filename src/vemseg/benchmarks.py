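"""Published benchmark Dice scores used as reference inputs.

Per-slice-averaged Dice scores of supervised and semi-supervised segmentation
models on three annotated FIB-SEM tumour-biopsy volumes, for nuclei and
nucleoli, at 7/10/15/25 training slices. These numbers are inputs (a printed
score grid), used to exercise :func:`vemseg.metrics.rank_models` and the
consistency checks in the acceptance script: the supervised-model summary
table reports an average of 0.9270 for UNet++ over its 24 (structure, volume,
n_train) settings, and the Volume-3 nucleoli gap between the semi-supervised
UNet++ with CutMix and the baseline ResUNet averages 0.11 Dice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "VOLUMES",
    "N_TRAIN",
    "SUPERVISED_MODELS",
    "NUCLEI_DICE",
    "NUCLEOLI_DICE",
    "score_frame",
    "supervised_score_frame",
]

VOLUMES = ("volume1", "volume2", "volume3")
N_TRAIN = (7, 10, 15, 25)

SUPERVISED_MODELS = (
    "ResUNet",
    "UNet++",
    "FracTALResNet",
    "CEECNet",
    "Senformer",
)

# rows: 12 values per model, ordered (volume1: 7,10,15,25 | volume2 | volume3)
NUCLEI_DICE = {
    "ResUNet": [0.9805, 0.9846, 0.9846, 0.9847, 0.9845, 0.9875, 0.9878, 0.9933, 0.9597, 0.9737, 0.9738, 0.9745],
    "UNet++": [0.9746, 0.9791, 0.9801, 0.9844, 0.9880, 0.9908, 0.9922, 0.9930, 0.9606, 0.9625, 0.9705, 0.9850],
    "FracTALResNet": [0.9724, 0.9796, 0.9817, 0.9885, 0.9756, 0.9836, 0.9871, 0.9887, 0.9655, 0.9698, 0.9760, 0.9825],
    "CEECNet": [0.9702, 0.9688, 0.9825, 0.9742, 0.9847, 0.9894, 0.9928, 0.9948, 0.9457, 0.9499, 0.9509, 0.9800],
    "Senformer": [0.9821, 0.9851, 0.9877, 0.9897, 0.9835, 0.9870, 0.9898, 0.9927, 0.9710, 0.9722, 0.9790, 0.9858],
    "SSL-ResUNet": [0.9880, 0.9889, 0.9882, 0.9902, 0.9938, 0.9931, 0.9941, 0.9958, 0.9703, 0.9702, 0.9770, 0.9822],
    "SSL-ResUNet-CutMix": [0.9892, 0.9898, 0.9903, 0.9912, 0.9951, 0.9952, 0.9954, 0.9957, 0.9726, 0.9747, 0.9799, 0.9822],
    "SSL-UNet++-CutMix": [0.9903, 0.9910, 0.9912, 0.9923, 0.9951, 0.9952, 0.9954, 0.9959, 0.9804, 0.9839, 0.9859, 0.9872],
}

NUCLEOLI_DICE = {
    "ResUNet": [0.9686, 0.9733, 0.9664, 0.9712, 0.8811, 0.9019, 0.9108, 0.9182, 0.7054, 0.7014, 0.6906, 0.7166],
    "UNet++": [0.9576, 0.9624, 0.9652, 0.9671, 0.8957, 0.9168, 0.9139, 0.9216, 0.6380, 0.7321, 0.7893, 0.8282],
    "FracTALResNet": [0.9662, 0.9613, 0.9464, 0.9671, 0.8809, 0.8778, 0.8775, 0.9237, 0.6892, 0.7547, 0.7677, 0.8307],
    "CEECNet": [0.9779, 0.9775, 0.9772, 0.9797, 0.7615, 0.8608, 0.8339, 0.8565, 0.5860, 0.6567, 0.7321, 0.8036],
    "Senformer": [0.9353, 0.9384, 0.9413, 0.9442, 0.8385, 0.8594, 0.8818, 0.9070, 0.6695, 0.6678, 0.7538, 0.8084],
    "SSL-ResUNet": [0.9775, 0.9783, 0.9767, 0.9782, 0.9007, 0.9196, 0.9344, 0.9401, 0.6714, 0.7447, 0.8041, 0.8176],
    "SSL-ResUNet-CutMix": [0.9781, 0.9782, 0.9787, 0.9791, 0.9193, 0.9218, 0.9339, 0.9440, 0.7763, 0.8013, 0.8159, 0.8266],
    "SSL-UNet++-CutMix": [0.9777, 0.9783, 0.9781, 0.9793, 0.9292, 0.9256, 0.9349, 0.9473, 0.7887, 0.8071, 0.8240, 0.8390],
}


def _columns(structure: str) -> list[tuple[str, str, int]]:
    return [(structure, v, n) for v in VOLUMES for n in N_TRAIN]


def score_frame(models=None) -> pd.DataFrame:
    """Full model × setting grid; columns are (structure, volume, n_train)."""
    models = list(models) if models is not None else list(NUCLEI_DICE)
    cols = pd.MultiIndex.from_tuples(
        _columns("nuclei") + _columns("nucleoli"),
        names=["structure", "volume", "n_train"],
    )
    data = np.array(
        [NUCLEI_DICE[m] + NUCLEOLI_DICE[m] for m in models], dtype=float
    )
    return pd.DataFrame(data, index=models, columns=cols)


def supervised_score_frame() -> pd.DataFrame:
    """Only the five fully-supervised architectures (the model-choice grid)."""
    return score_frame(SUPERVISED_MODELS)
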