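"""Training loops, CPS equivalences, state persistence, tiled inference."""

import numpy as np
import pytest

from vemseg.autograd import Tensor
from vemseg.losses import WarmupSchedule
from vemseg.metrics import evaluate_volume
from vemseg.models import ModelConfig, build_model
from vemseg.sampling import SamplerConfig, sample_training_batch, select_labeled_slices
from vemseg.trainer import (
    CPSTrainConfig,
    SymmetrizedNet,
    TrainConfig,
    init_supervised_state,
    load_train_state,
    predict_volume,
    run_steps,
    save_train_state,
    train_cps,
    train_supervised,
)

MODEL = ModelConfig(arch="resunet", base_width=6, depth=2)
SAMPLER = SamplerConfig(
    context_size=64, out_size=32, foreground_fraction=0.99, augment=True, rng_seed=0
)
INFER = SamplerConfig(context_size=64, out_size=32)


@pytest.fixture(scope="module")
def train_volume(request):
    from conftest import small_spec
    from vemseg.synthdata import generate_volume

    vol = generate_volume(small_spec(noise_sd=0.02, seed=5))
    return vol.with_labeled_slices(select_labeled_slices(5, vol.n_slices))


@pytest.fixture(scope="module")
def converged_net(train_volume):
    """One supervised network trained to convergence on the clean volume,
    shared by the convergence and inference tests."""
    cfg = TrainConfig(steps=250, batch_size=2, lr=2e-3, seed=0, sampler=SAMPLER)
    net, log = train_supervised(train_volume, "nuclei", MODEL, cfg)
    return net, log


def test_zero_steps_returns_initialization(train_volume):
    cfg = TrainConfig(steps=0, batch_size=2, seed=3, sampler=SAMPLER)
    net, log = train_supervised(train_volume, "nuclei", MODEL, cfg)
    ref = build_model(MODEL, seed=3)
    assert log == []
    for a, b in zip(net.parameters(), ref.parameters()):
        np.testing.assert_array_equal(a.data, b.data)


def test_training_loss_decreases(converged_net):
    _, log = converged_net
    first = np.mean([e["loss"] for e in log[:20]])
    last = np.mean([e["loss"] for e in log[-20:]])
    assert last < 0.1
    assert last < first / 3


def test_batches_drawn_from_selected_slices_only(train_volume):
    sel = set(train_volume.labeled_slices)
    rng = np.random.default_rng(0)
    for _ in range(10):
        batch = sample_training_batch(train_volume, "nuclei", 4, SAMPLER, rng)
        assert {z for z, *_ in batch.provenance} <= sel


def test_stitched_prediction_recovers_structure(train_volume, converged_net):
    net, _ = converged_net
    pred, conf = predict_volume(net, train_volume, INFER)
    rep = evaluate_volume(pred, train_volume.labels["nuclei"])
    assert rep.dice3d >= 0.95
    assert conf.shape == train_volume.intensities.shape
    assert conf.min() >= 0.0 and conf.max() <= 1.0


def test_uniform_confidence_predicts_background(train_volume):
    class _Uniform:
        config = MODEL

        def eval(self):
            return self

        def confidences(self, x):
            b, _, h, w = x.shape
            return Tensor(np.full((b, 2, h, w), 0.5, dtype=np.float32))

    pred, conf = predict_volume(_Uniform(), train_volume, INFER)
    assert pred.sum() == 0  # ties break toward background
    np.testing.assert_allclose(conf, 0.5)


def test_symmetrized_inference_commutes_with_rotation(train_volume, converged_net):
    net, _ = converged_net
    wrapped = SymmetrizedNet(net, transforms=(0, 2))
    pred, _ = predict_volume(wrapped, train_volume, INFER)
    rot = train_volume.with_labeled_slices([])
    rot.intensities = np.ascontiguousarray(np.rot90(train_volume.intensities, 2, axes=(1, 2)))
    pred_rot, _ = predict_volume(wrapped, rot, INFER)
    np.testing.assert_array_equal(np.rot90(pred_rot, 2, axes=(1, 2)), pred)


def test_cps_lambda_zero_reproduces_two_supervised_runs(train_volume):
    """With the CPS weight held at zero, the pair trains exactly like two
    independent supervised runs seeded with seed and seed + 1."""
    steps = 25
    cps_cfg = CPSTrainConfig(
        steps=steps,
        batch_size_labeled=2,
        batch_size_cps=2,
        schedule=WarmupSchedule(lambda_max=0.0, warmup_steps=0),
        cutmix=True,
        seed=11,
        sampler=SAMPLER,
    )
    n1, n2, clog = train_cps(train_volume, "nuclei", cps_cfg, MODEL)
    for k, seed in enumerate((11, 12)):
        sup_cfg = TrainConfig(steps=steps, batch_size=2, seed=seed, sampler=SAMPLER)
        _, slog = train_supervised(train_volume, "nuclei", MODEL, sup_cfg)
        sup_losses = [e["loss"] for e in slog]
        cps_losses = [e[f"sup{k + 1}"] for e in clog]
        np.testing.assert_allclose(cps_losses, sup_losses, atol=1e-6)
    assert all(e["cps"] == 0.0 for e in clog)


def test_cps_contributes_no_gradient_at_step_zero(train_volume):
    """lambda(0) = 0 under a warm-up: the first step must ignore the CPS term."""
    cfg = CPSTrainConfig(
        steps=1,
        batch_size_labeled=2,
        batch_size_cps=2,
        schedule=WarmupSchedule(1.0, 50),
        seed=2,
        sampler=SAMPLER,
    )
    _, _, log = train_cps(train_volume, "nuclei", cfg, MODEL)
    assert log[0]["lambda"] == 0.0
    assert log[0]["cps"] == 0.0


def test_cps_losses_logged_after_warmup(train_volume):
    cfg = CPSTrainConfig(
        steps=6,
        batch_size_labeled=2,
        batch_size_cps=2,
        schedule=WarmupSchedule(1.0, 2),
        cutmix=True,
        seed=2,
        sampler=SAMPLER,
    )
    _, _, log = train_cps(train_volume, "nuclei", cfg, MODEL)
    lams = [e["lambda"] for e in log]
    assert lams == [0.0, 0.5, 1.0, 1.0, 1.0, 1.0]
    assert all(e["cps"] > 0 for e in log[1:])


def test_save_load_continue_matches_uninterrupted_run(train_volume, tmp_path):
    cfg = TrainConfig(steps=0, batch_size=2, seed=7, sampler=SAMPLER)

    full = init_supervised_state(MODEL, cfg)
    run_steps(full, train_volume, "nuclei", 30)

    half = init_supervised_state(MODEL, cfg)
    run_steps(half, train_volume, "nuclei", 15)
    p = save_train_state(tmp_path / "state", half)
    resumed = load_train_state(p)
    run_steps(resumed, train_volume, "nuclei", 15)

    full_losses = [e["loss"] for e in full.log]
    resumed_losses = [e["loss"] for e in resumed.log]
    np.testing.assert_allclose(resumed_losses, full_losses, atol=1e-6)


def test_save_load_cps_state(train_volume, tmp_path):
    from vemseg.trainer import init_cps_state

    cfg = CPSTrainConfig(
        steps=0, batch_size_labeled=2, batch_size_cps=2,
        schedule=WarmupSchedule(1.0, 4), seed=3, sampler=SAMPLER,
    )
    full = init_cps_state(MODEL, cfg)
    run_steps(full, train_volume, "nuclei", 12)

    half = init_cps_state(MODEL, cfg)
    run_steps(half, train_volume, "nuclei", 6)
    resumed = load_train_state(save_train_state(tmp_path / "cps", half))
    run_steps(resumed, train_volume, "nuclei", 6)

    for key in ("sup1", "sup2", "cps"):
        np.testing.assert_allclose(
            [e[key] for e in resumed.log], [e[key] for e in full.log], atol=1e-6
        )


def test_training_without_labeled_slices_rejected(small_volume):
    vol = small_volume.with_labeled_slices([])
    with pytest.raises(ValueError, match="labeled"):
        train_supervised(vol, "nuclei", MODEL, TrainConfig(steps=1, sampler=SAMPLER))


def test_unknown_structure_rejected(train_volume):
    with pytest.raises(KeyError, match="mitochondria"):
        train_supervised(
            train_volume, "mitochondria", MODEL, TrainConfig(steps=1, sampler=SAMPLER)
        )
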