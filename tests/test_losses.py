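"""Soft Dice, pseudo-labels, CPS loss, warm-up schedule and CutMix."""

import numpy as np
import pytest

from vemseg.autograd import Tensor, concat, softmax
from vemseg.losses import (
    CutMixBox,
    WarmupSchedule,
    batch_soft_dice_loss,
    cps_loss,
    cutmix_apply,
    lambda_at,
    mix_with_mask,
    pseudo_label,
    sample_cutmix_box,
    soft_dice_loss,
)


def dice_loss_oracle(y, p, eps):
    """Brute-force elementwise-sum evaluation of the smoothed Dice loss."""
    inter = 0.0
    sy = 0.0
    sp = 0.0
    for yi, pi in zip(np.ravel(y).tolist(), np.ravel(p).tolist()):
        inter += yi * pi
        sy += yi
        sp += pi
    return 1.0 - (2.0 * inter + eps) / (sy + sp + eps)


class TestSoftDice:
    def test_perfect_prediction_is_zero(self, rng):
        y = (rng.random((12, 12)) > 0.6).astype(np.float32)
        assert soft_dice_loss(y, y).item() == pytest.approx(0.0, abs=1e-6)

    def test_empty_empty_is_zero_under_smoothing(self):
        z = np.zeros((8, 8), dtype=np.float32)
        assert soft_dice_loss(z, z, eps=1.0).item() == pytest.approx(0.0)

    def test_half_confidence_on_full_mask_is_one_third(self):
        n = 128
        y = np.ones((n, n), dtype=np.float32)
        p = np.full((n, n), 0.5, dtype=np.float32)
        assert soft_dice_loss(y, p, eps=1e-7).item() == pytest.approx(1 / 3, abs=1e-4)

    def test_matches_bruteforce_on_randomized_masks(self, rng):
        for _ in range(25):
            y = (rng.random((7, 9)) > rng.random()).astype(np.float32)
            p = rng.random((7, 9)).astype(np.float32)
            eps = float(rng.choice([1e-6, 0.5, 1.0]))
            got = soft_dice_loss(y, p, eps=eps).item()
            assert got == pytest.approx(dice_loss_oracle(y, p, eps), abs=1e-6)

    def test_bounded_and_monotone_in_overlap(self, rng):
        y = (rng.random((16, 16)) > 0.5).astype(np.float32)
        p_bad = rng.random((16, 16)).astype(np.float32) * (1 - y)
        p_good = np.clip(p_bad + 0.9 * y, 0, 1)
        lb, lg = soft_dice_loss(y, p_bad).item(), soft_dice_loss(y, p_good).item()
        assert 0.0 <= lg < lb <= 1.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            soft_dice_loss(np.zeros((4, 4)), np.zeros((4, 5)))

    def test_batch_version_averages_per_crop(self, rng):
        y = (rng.random((3, 8, 8)) > 0.5).astype(np.float32)
        p = rng.random((3, 8, 8)).astype(np.float32)
        per_crop = [soft_dice_loss(y[i], p[i]).item() for i in range(3)]
        assert batch_soft_dice_loss(y, p).item() == pytest.approx(
            np.mean(per_crop), abs=1e-6
        )


class TestPseudoLabel:
    def test_one_hot_recovers_class_map(self):
        conf = np.zeros((2, 3, 3), dtype=np.float32)
        target = np.array([[0, 1, 0], [1, 1, 0], [0, 0, 1]])
        conf[1] = target
        conf[0] = 1 - target
        np.testing.assert_array_equal(pseudo_label(conf), target)

    def test_tie_goes_to_background(self):
        conf = np.full((2, 4, 4), 0.5, dtype=np.float32)
        assert (pseudo_label(conf) == 0).all()

    def test_three_class_matches_bruteforce(self, rng):
        conf = rng.random((3, 5, 6)).astype(np.float32)
        got = pseudo_label(conf)
        for i in range(5):
            for j in range(6):
                best, cls = -1.0, -1
                for c in range(3):
                    if conf[c, i, j] > best:  # first maximum wins
                        best, cls = conf[c, i, j], c
                assert got[i, j] == cls

    def test_stop_gradient_contract(self):
        t = Tensor(np.random.default_rng(0).random((1, 2, 4, 4)), requires_grad=True)
        pl = pseudo_label(t)
        assert isinstance(pl, np.ndarray)  # a constant, not part of the tape


def _two_param_confidences(theta1, theta2, x_img):
    """Toy pair of 'networks': class-1 logit = theta_k * image, class-0 = 0."""
    confs = []
    for th in (theta1, theta2):
        logit = Tensor(x_img[None, None]) * th
        zeros = logit * 0.0
        confs.append(softmax(concat([zeros, logit], axis=1), axis=1))
    return confs


class TestCPSLoss:
    def test_zero_at_one_hot_agreement(self):
        m = np.zeros((1, 2, 4, 4), dtype=np.float32)
        m[:, 1, :2] = 1.0
        m[:, 0, 2:] = 1.0
        assert cps_loss(Tensor(m), Tensor(m)).item() == pytest.approx(0.0, abs=1e-6)

    def test_total_disagreement_is_about_two(self):
        fg = np.zeros((1, 2, 8, 8), dtype=np.float32)
        fg[:, 1] = 1.0
        bg = np.zeros((1, 2, 8, 8), dtype=np.float32)
        bg[:, 0] = 1.0
        # each direction's Dice loss is ~1 (smoothing makes it slightly less)
        total = cps_loss(Tensor(fg), Tensor(bg), eps=1e-3).item()
        assert total == pytest.approx(2.0, abs=0.01)

    def test_symmetric_in_its_arguments(self, rng):
        a = Tensor(rng.random((2, 2, 6, 6)).astype(np.float32))
        b = Tensor(rng.random((2, 2, 6, 6)).astype(np.float32))
        assert cps_loss(a, b).item() == pytest.approx(cps_loss(b, a).item(), abs=1e-7)

    def test_zero_gradient_through_pseudo_label_path(self, rng):
        """Perturbing the pseudo-label producer must not change the loss term
        it supervises: finite differences against the autograd gradient."""
        x_img = rng.normal(size=(6, 6)).astype(np.float32) + 0.5
        theta1 = Tensor(np.array(0.8), requires_grad=True)
        theta2 = Tensor(np.array(1.3), requires_grad=True)

        def term1(t2_val):
            th2 = Tensor(np.array(t2_val), requires_grad=True)
            c1, c2 = _two_param_confidences(theta1, th2, x_img)
            fg2 = (pseudo_label(c2) == 1).astype(np.float32)
            return batch_soft_dice_loss(fg2, c1[:, 1])

        # autograd: term1 has no path into theta2
        theta1.zero_grad()
        theta2.zero_grad()
        c1, c2 = _two_param_confidences(theta1, theta2, x_img)
        fg2 = (pseudo_label(c2) == 1).astype(np.float32)
        batch_soft_dice_loss(fg2, c1[:, 1]).backward()
        assert theta2.grad is None
        assert theta1.grad is not None and abs(float(theta1.grad)) > 0

        # finite differences: the pseudo-label is piecewise constant in theta2
        eps = 1e-3
        fd = (term1(1.3 + eps).item() - term1(1.3 - eps).item()) / (2 * eps)
        assert fd == pytest.approx(0.0, abs=1e-8)


class TestWarmup:
    def test_schedule_values(self):
        s = WarmupSchedule(lambda_max=1.0, warmup_steps=100)
        assert lambda_at(0, s) == 0.0
        assert lambda_at(50, s) == pytest.approx(0.5)
        assert lambda_at(100, s) == 1.0
        assert lambda_at(10_000, s) == 1.0

    def test_no_warmup_means_constant(self):
        s = WarmupSchedule(lambda_max=0.7, warmup_steps=0)
        assert lambda_at(0, s) == pytest.approx(0.7)

    def test_non_decreasing_piecewise_linear(self):
        s = WarmupSchedule(lambda_max=2.0, warmup_steps=37)
        vals = [lambda_at(t, s) for t in range(80)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert vals[37] == pytest.approx(2.0)
        # linear increments during warm-up
        incs = np.diff(vals[:37])
        np.testing.assert_allclose(incs, 2.0 / 37, rtol=1e-5)


class _FixedRng:
    """Stub generator with scripted uniform draws."""

    def __init__(self, ratio):
        self.ratio = ratio

    def random(self):
        return self.ratio

    def integers(self, lo, hi):
        return lo


class TestCutMix:
    def test_zero_area_box_returns_first_batch(self, rng):
        a = rng.random((3, 1, 8, 8)).astype(np.float32)
        b = rng.random((3, 1, 8, 8)).astype(np.float32)
        mixed, mask = cutmix_apply(a, b, CutMixBox(0, 0, 0, 0))
        np.testing.assert_array_equal(mixed, a)
        assert mask.sum() == 0

    def test_full_box_returns_second_batch(self, rng):
        a = rng.random((2, 1, 8, 8)).astype(np.float32)
        b = rng.random((2, 1, 8, 8)).astype(np.float32)
        mixed, mask = cutmix_apply(a, b, CutMixBox(0, 0, 8, 8))
        np.testing.assert_array_equal(mixed, b)
        assert mask.sum() == 64

    def test_pixel_conservation(self, rng):
        a = rng.random((1, 1, 8, 8)).astype(np.float32)
        b = rng.random((1, 1, 8, 8)).astype(np.float32)
        box = CutMixBox(2, 3, 4, 2)
        mixed, mask = cutmix_apply(a, b, box)
        inside = mask.astype(bool)
        expected = sorted(a[0, 0][~inside].tolist() + b[0, 0][inside].tolist())
        assert sorted(mixed[0, 0].ravel().tolist()) == expected

    def test_complementary_mix_recovers_originals(self, rng):
        a = rng.random((2, 1, 8, 8)).astype(np.float32)
        b = rng.random((2, 1, 8, 8)).astype(np.float32)
        box = CutMixBox(1, 1, 5, 6)
        ab, mask = cutmix_apply(a, b, box)
        ba, _ = cutmix_apply(b, a, box)
        np.testing.assert_array_equal(mix_with_mask(ab, ba, mask), a)
        np.testing.assert_array_equal(mix_with_mask(ba, ab, mask), b)

    def test_box_outside_crop_rejected(self, rng):
        a = rng.random((1, 1, 8, 8)).astype(np.float32)
        with pytest.raises(ValueError, match="box"):
            cutmix_apply(a, a, CutMixBox(5, 5, 6, 6))

    def test_forced_extreme_ratios(self):
        assert sample_cutmix_box(32, _FixedRng(0.0)).h == 0
        box = sample_cutmix_box(32, _FixedRng(1.0))
        assert (box.h, box.w) == (32, 32)

    def test_mean_area_ratio_is_half(self):
        rng = np.random.default_rng(99)
        crop = 101
        ratios = []
        for _ in range(10_000):
            box = sample_cutmix_box(crop, rng)
            ratios.append(box.h * box.w / crop**2)
        # area ratio ~ U(0,1): mean 0.5, se = sqrt(1/12)/100
        assert np.mean(ratios) == pytest.approx(0.5, abs=3 * 0.00289 + 0.005)
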