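"""Loss formulas, augmentation pairing, folds, and the optimization loop."""

import math

import numpy as np
import pytest

import oracles
from phasepaint import training
from phasepaint.errors import ConfigurationError, DataError, DimensionError
from phasepaint.segnet import NetworkConfig, load_checkpoint, save_checkpoint
from phasepaint.training import (
    AugmentConfig,
    TrainConfig,
    augment,
    combined_loss,
    dice_loss,
    focal_loss,
    hflip,
    make_folds,
    train,
    vflip,
)

TINY = NetworkConfig(n_stages=2, base_channels=8, cardinality=2, se_reduction=2,
                     dropout_p=0.0, norm="group")


class TestFocalLoss:
    def test_single_pixel_hand_value(self):
        # y=1, p=0.5, gamma=2: (1-0.5)^2 * (-log 0.5) = 0.25 * 0.693147
        val = focal_loss(np.array([[0.5]]), np.array([[1.0]]), gamma=2.0)
        assert val == pytest.approx(0.25 * math.log(2.0), abs=1e-9)

    def test_reduces_to_bce_in_small_gamma_limit(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, (8, 8))
        y = rng.integers(0, 2, (8, 8)).astype(float)
        bce = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert focal_loss(p, y, gamma=1e-12) == pytest.approx(bce, abs=1e-9)

    def test_perfect_prediction_is_near_zero(self):
        y = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert focal_loss(y, y, gamma=2.0) < 1e-6

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.uniform(0.01, 0.99, (6, 6))
            y = rng.integers(0, 2, (6, 6)).astype(float)
            g = rng.uniform(0.5, 4.0)
            assert focal_loss(p, y, g) == pytest.approx(
                oracles.focal_loop(p, y, g), abs=1e-9
            )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            focal_loss(np.zeros((2, 2)), np.zeros((2, 2)), gamma=0.0)
        with pytest.raises(DimensionError):
            focal_loss(np.zeros((2, 2)), np.zeros((3, 3)))


class TestDiceLoss:
    def test_perfect_nonempty_match_is_minus_one(self):
        y = np.array([1.0, 1.0, 0.0])
        assert dice_loss(y, y) == pytest.approx(-1.0, abs=1e-6)

    def test_disjoint_supports_give_zero(self):
        assert dice_loss(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_printed_form_hand_example(self):
        y = np.array([1.0, 1.0, 0.0, 0.0])
        p = np.array([1.0, 0.0, 1.0, 0.0])
        assert dice_loss(p, y) == pytest.approx(-0.5, abs=1e-6)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.uniform(0, 1, (5, 5))
            y = rng.integers(0, 2, (5, 5)).astype(float)
            assert dice_loss(p, y) == pytest.approx(
                oracles.dice_loss_loop(p, y), abs=1e-9
            )


class TestCombinedLoss:
    def test_weight_extremes_select_each_component(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.01, 0.99, (4, 4))
        y = rng.integers(0, 2, (4, 4)).astype(float)
        cfg_f = TrainConfig(loss_weights=(1.0, 0.0))
        cfg_d = TrainConfig(loss_weights=(0.0, 1.0))
        assert combined_loss(p, y, cfg_f) == pytest.approx(
            focal_loss(p, y, cfg_f.gamma), abs=1e-12
        )
        assert combined_loss(p, y, cfg_d) == pytest.approx(dice_loss(p, y), abs=1e-12)

    def test_perfect_prediction_approaches_minus_one(self):
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert combined_loss(y, y, TrainConfig()) == pytest.approx(-1.0, abs=1e-5)

    def test_degenerate_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            TrainConfig(loss_weights=(0.0, 0.0))


class TestAugment:
    def test_all_toggles_off_is_identity(self):
        rng = np.random.default_rng(4)
        img = rng.random((32, 32))
        mask = rng.integers(0, 2, (32, 32)).astype(float)
        out_img, out_mask = augment(img, mask, seed=0, config=AugmentConfig.none())
        np.testing.assert_array_equal(out_img, img)
        np.testing.assert_array_equal(out_mask, mask)

    def test_flips_are_involutions(self):
        arr = np.random.default_rng(5).random((8, 8))
        np.testing.assert_array_equal(hflip(hflip(arr)), arr)
        np.testing.assert_array_equal(vflip(vflip(arr)), arr)

    def test_flip_only_augmentation_preserves_foreground_count(self):
        cfg = AugmentConfig.none()
        cfg.hflip = cfg.vflip = True
        rng = np.random.default_rng(6)
        mask = rng.integers(0, 2, (16, 16)).astype(float)
        img = rng.random((16, 16))
        for seed in range(8):
            _, out_mask = augment(img, mask, seed=seed, config=cfg)
            assert out_mask.sum() == mask.sum()

    def test_mask_stays_binary_and_receives_no_photometric_noise(self):
        rng = np.random.default_rng(7)
        img = rng.random((32, 32))
        mask = rng.integers(0, 2, (32, 32)).astype(float)
        for seed in range(5):
            out_img, out_mask = augment(img, mask, seed=seed)
            assert out_img.shape == img.shape and out_mask.shape == mask.shape
            assert set(np.unique(out_mask)) <= {0.0, 1.0}

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            augment(np.zeros((4, 4)), np.zeros((5, 5)))


class TestMakeFolds:
    def test_even_split_sizes_and_exhaustiveness(self):
        folds = make_folds(10, 5, seed=0)
        val_sizes = sorted(len(v) for _, v in folds)
        assert val_sizes == [2, 2, 2, 2, 2]
        union = np.sort(np.concatenate([v for _, v in folds]))
        np.testing.assert_array_equal(union, np.arange(10))

    def test_uneven_split_sizes_by_pigeonhole(self):
        folds = make_folds(7, 5, seed=1)
        assert sorted(len(v) for _, v in folds) == [1, 1, 1, 2, 2]

    def test_train_and_validation_are_disjoint(self):
        for tr, va in make_folds(13, 4, seed=2):
            assert not set(tr) & set(va)

    def test_deterministic_given_seed(self):
        a = make_folds(12, 3, seed=5)
        b = make_folds(12, 3, seed=5)
        for (ta, va), (tb, vb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(va, vb)

    def test_too_few_items_rejected(self):
        with pytest.raises(ConfigurationError):
            make_folds(4, 5)


class TestLRSchedule:
    def test_paper_recipe_drops_by_ten_after_epochs_10_and_20(self):
        cfg = TrainConfig()
        lrs = [cfg.lr_at_epoch(e) for e in range(1, 31)]
        assert all(lr == pytest.approx(3e-4) for lr in lrs[:10])
        assert all(lr == pytest.approx(3e-5) for lr in lrs[10:20])
        assert all(lr == pytest.approx(3e-6) for lr in lrs[20:30])


class TestTrainLoop:
    def test_loss_decreases_over_five_epochs(self, nuclei_tiles):
        x, y = nuclei_tiles
        cfg = TrainConfig(n_epochs=5, batch_size=8, seed=0,
                          augment=AugmentConfig.none())
        model, hist = train((x[:32], y[:32]), TINY, cfg)
        assert len(hist.epoch_loss) == 5
        assert hist.epoch_loss[4] < hist.epoch_loss[0]
        # recorded LR sequence is non-increasing
        assert all(a >= b for a, b in zip(hist.lr, hist.lr[1:]))

    def test_checkpoint_reload_reproduces_outputs(self, nuclei_tiles, tmp_path):
        x, y = nuclei_tiles
        cfg = TrainConfig(n_epochs=1, batch_size=8, seed=1,
                          augment=AugmentConfig.none())
        model, _ = train((x[:16], y[:16]), TINY, cfg)
        ref = model.predict(x[:4])
        save_checkpoint(tmp_path / "m.npz", model)
        back, _ = load_checkpoint(tmp_path / "m.npz")
        np.testing.assert_array_equal(back.predict(x[:4]), ref)

    def test_empty_and_oversized_batch_rejected(self):
        with pytest.raises(DataError):
            train((np.empty((0, 8, 8)), np.empty((0, 8, 8))), TINY, TrainConfig())
        with pytest.raises(DataError):
            train(
                (np.zeros((4, 8, 8)), np.zeros((4, 8, 8))),
                TINY,
                TrainConfig(batch_size=24),
            )
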