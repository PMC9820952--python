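import numpy as np
import pytest

from masseg.network import NetworkConfig
from masseg.training import (TrainConfig, augment, combined_loss,
                             combined_loss_and_grad, cross_entropy,
                             deep_supervision_loss, downsample_labels, lr_at,
                             one_hot, sample_affine, soft_dice_loss, train)

TINY_NET = NetworkConfig(channels=(3, 4, 5, 6), rsu_depths=(1, 1, 1, 1),
                         mid_channels=(2, 2, 2, 2))


class TestSoftDice:
    def test_perfect_prediction(self):
        y = np.random.default_rng(0).integers(0, 3, size=(6, 6, 6))
        g = one_hot(y, 3)
        assert soft_dice_loss(g, g) <= 1e-4

    def test_total_miss(self):
        y = np.zeros((6, 6, 6), np.int64)
        y[:3] = 1
        g = one_hot(y, 2)
        complement = g[..., ::-1].copy()
        assert soft_dice_loss(complement, g) >= 1 - 1e-4

    def test_half_probability_closed_form(self):
        # single class: p = 0.5 everywhere, g = 1 on half the voxels
        # dice = 2*(0.25N)/(0.5N + 0.5N) = 0.5 -> loss 0.5
        n = 64
        p = np.full((n, 1), 0.5)
        g = np.zeros((n, 1))
        g[: n // 2] = 1.0
        assert soft_dice_loss(p, g) == pytest.approx(0.5, abs=1e-4)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            soft_dice_loss(np.zeros((4, 3)), np.zeros((5, 3)))


class TestCombinedLoss:
    def test_saturated_perfect_prediction_near_zero(self):
        y = np.random.default_rng(1).integers(0, 3, size=(6, 6, 6))
        scores = 50.0 * one_hot(y, 3)
        assert combined_loss(scores, y) < 1e-3

    def test_uniform_scores_cross_entropy_ln3(self):
        y = np.random.default_rng(2).integers(0, 3, size=(8, 8, 8))
        scores = np.zeros(y.shape + (3,))
        probs = np.full(y.shape + (3,), 1 / 3)
        ce = cross_entropy(probs, y)
        assert ce == pytest.approx(np.log(3), rel=1e-9)
        total = combined_loss(scores, y)
        assert total == pytest.approx(ce + soft_dice_loss(probs, one_hot(y, 3)), rel=1e-6)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(4, 4, 4, 3))
        y = rng.integers(0, 3, size=(4, 4, 4))
        loss, grad = combined_loss_and_grad(scores, y)
        eps = 1e-5
        for _ in range(6):
            idx = tuple(rng.integers(0, s) for s in scores.shape)
            sp = scores.copy(); sp[idx] += eps
            sm = scores.copy(); sm[idx] -= eps
            fd = (combined_loss(sp, y) - combined_loss(sm, y)) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, rel=1e-3, abs=1e-8)


class TestDeepSupervision:
    def _outputs(self, rng, full=8):
        y = rng.integers(0, 3, size=(1, full, full, full))
        outs = [rng.normal(size=(1, full // 2**s, full // 2**s, full // 2**s, 3))
                for s in range(3)]
        return outs, y

    def test_single_output_equals_combined_loss(self):
        rng = np.random.default_rng(4)
        outs, y = self._outputs(rng)
        single = deep_supervision_loss([outs[0]], y)
        assert single == pytest.approx(combined_loss(outs[0], y), rel=1e-12)

    def test_k_identical_outputs_scale_linearly(self):
        rng = np.random.default_rng(5)
        outs, y = self._outputs(rng)
        one = deep_supervision_loss([outs[0]], y)
        three = deep_supervision_loss([outs[0]] * 3, y)
        assert three == pytest.approx(3 * one, rel=1e-12)

    def test_zero_weights_select_finest_scale(self):
        rng = np.random.default_rng(6)
        outs, y = self._outputs(rng)
        sel = deep_supervision_loss(outs, y, weights=(1.0, 0.0, 0.0))
        assert sel == pytest.approx(combined_loss(outs[0], y), rel=1e-12)

    def test_downsampling_is_nearest_neighbor(self):
        y = np.arange(8).reshape(2, 2, 2)[None] % 3
        down = downsample_labels(y, 2)
        np.testing.assert_array_equal(down, y[:, ::2, ::2, ::2])

    def test_mismatched_resolution_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            deep_supervision_loss([np.zeros((1, 3, 3, 3, 3))],
                                  np.zeros((1, 8, 8, 8), np.int64))


class TestSchedule:
    CFG = TrainConfig(total_iterations=20000, warmup_iterations=300, base_lr=1e-3)

    @pytest.mark.parametrize("it,expected", [
        (0, 0.0),
        (150, 5e-4),     # linear warm-up midpoint
        (300, 1e-3),     # warm-up endpoint reaches base_lr
        (10150, 5e-4),   # cosine decay midpoint: cos(pi/2) = 0
        (20000, 0.0),
    ])
    def test_closed_form_points(self, it, expected):
        assert lr_at(it, self.CFG) == pytest.approx(expected, abs=1e-12)

    def test_continuous_and_peaks_at_warmup(self):
        lrs = np.array([lr_at(i, self.CFG) for i in range(0, 20001, 10)])
        assert np.argmax(lrs) == 30  # iteration 300
        assert np.max(np.abs(np.diff(lrs))) < 5e-5

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lr_at(-1, self.CFG)
        with pytest.raises(ValueError):
            lr_at(20001, self.CFG)


class TestAugment:
    def test_identity_for_degenerate_ranges(self):
        cfg = TrainConfig(rotation_deg=0.0, scale_range=(1.0, 1.0))
        rng = np.random.default_rng(0)
        v = rng.normal(size=(8, 8, 8)).astype(np.float32)
        l = rng.integers(0, 3, size=(8, 8, 8)).astype(np.uint8)
        v2, l2 = augment(v, l, cfg, rng)
        np.testing.assert_array_equal(v, v2)
        np.testing.assert_array_equal(l, l2)

    def test_never_a_reflection_over_many_draws(self):
        cfg = TrainConfig()
        rng = np.random.default_rng(1)
        for _ in range(150):
            assert np.linalg.det(sample_affine(cfg, rng)) > 0

    def test_same_seed_reproduces_transform(self):
        cfg = TrainConfig()
        v = np.random.default_rng(2).normal(size=(12, 12, 12)).astype(np.float32)
        l = (v > 0).astype(np.uint8)
        a = augment(v, l, cfg, np.random.default_rng(7))
        b = augment(v, l, cfg, np.random.default_rng(7))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_left_structure_stays_on_left(self):
        # a blob on the +x side keeps a +x centroid under +-15 deg / 0.85-1.15x
        cfg = TrainConfig()
        rng = np.random.default_rng(3)
        lab = np.zeros((32, 32, 32), np.uint8)
        lab[24:29, 14:18, 14:18] = 1
        vol = lab.astype(np.float32)
        cx = (32 - 1) / 2
        for _ in range(100):
            _, l2 = augment(vol, lab, cfg, rng)
            assert l2.sum() > 0
            assert np.argwhere(l2 == 1)[:, 0].mean() > cx


class TestTrainLoop:
    def _samples(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(16, 16, 16)).astype(np.float32)
        lab = np.zeros((16, 16, 16), np.uint8)
        lab[4:9, 10:14, 6:10] = 1
        lab[4:9, 2:6, 6:10] = 2
        return [(img, lab)]

    def test_ten_iterations_bitwise_reproducible(self):
        cfg = TrainConfig(total_iterations=10, warmup_iterations=2, patch_size=8,
                          seed=5)
        _, log1 = train(self._samples(), TINY_NET, cfg)
        _, log2 = train(self._samples(), TINY_NET, cfg)
        assert log1 == log2

    def test_logged_lr_follows_schedule(self):
        cfg = TrainConfig(total_iterations=10, warmup_iterations=2, patch_size=8,
                          seed=1)
        _, log = train(self._samples(), TINY_NET, cfg)
        for row in log:
            assert row["lr"] == pytest.approx(lr_at(row["iteration"], cfg))

    def test_empty_dataset_rejected(self):
        cfg = TrainConfig(total_iterations=5, warmup_iterations=1, patch_size=8)
        with pytest.raises(ValueError, match="empty"):
            train([], TINY_NET, cfg)
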