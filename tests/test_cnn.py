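"""Encoding, augmentation, training and inference of the patch classifier."""

import numpy as np
import pytest

from nemadetect.cnn import (
    ClassifierModel,
    TrainConfig,
    augment,
    cross_entropy,
    encode_roi,
    predict,
    reflect_patch,
    rotate_patch,
    train,
)
from nemadetect.fields import ParameterError
from nemadetect.records import CLASSES
from nemadetect.synthetic import LabeledDataset, generate_labeled_rois
from nemadetect.winding import classify_roi_winding

from conftest import ideal_patch


class TestEncoding:
    def test_axis_aligned_patches(self):
        x = encode_roi(np.zeros((9, 9)))
        assert np.allclose(x[0], 1.0) and np.allclose(x[1], 0.0)
        y = encode_roi(np.full((9, 9), np.pi / 2))
        assert np.allclose(y[0], -1.0) and np.allclose(y[1], 0.0)

    def test_head_tail_symmetry_is_exact(self):
        rng = np.random.default_rng(0)
        patch = rng.uniform(0, np.pi, (9, 9))
        assert np.allclose(encode_roi(patch), encode_roi(patch + np.pi))

    def test_values_bounded(self):
        rng = np.random.default_rng(1)
        x = encode_roi(rng.uniform(0, np.pi, (9, 9)))
        assert np.abs(x).max() <= 1.0


class TestAugmentation:
    def test_eightfold_and_label_preserving(self):
        ds = generate_labeled_rois(6, (None,), seed=5)
        aug = augment(ds)
        assert len(aug) == 8 * len(ds)
        assert np.array_equal(
            np.bincount(aug.labels, minlength=3),
            8 * np.bincount(ds.labels, minlength=3),
        )

    def test_four_rotations_compose_to_identity(self):
        rng = np.random.default_rng(2)
        patch = rng.uniform(0, np.pi, (9, 9))
        out = patch
        for _ in range(4):
            out = rotate_patch(out, 1)
        assert np.allclose(np.exp(2j * out), np.exp(2j * patch), atol=1e-12)

    def test_reflection_is_an_involution(self):
        rng = np.random.default_rng(3)
        patch = rng.uniform(0, np.pi, (9, 9))
        assert np.allclose(
            np.exp(2j * reflect_patch(reflect_patch(patch))),
            np.exp(2j * patch), atol=1e-12,
        )

    def test_augmented_copies_keep_winding_class(self):
        ds = LabeledDataset(
            patches=[ideal_patch(0.5, phase=0.4)], labels=[0]
        )
        for patch in augment(ds).patches:
            assert classify_roi_winding(patch) == "+1/2"

    def test_non_square_patches_rejected_at_construction(self):
        from nemadetect.synthetic import ConfigError

        with pytest.raises(ConfigError):
            LabeledDataset(patches=np.zeros((2, 9, 7)), labels=[0, 1])


class TestLossArithmetic:
    def test_perfect_prediction_contributes_zero(self):
        probs = np.array([[1.0, 0.0, 0.0]])
        y = np.array([[1.0, 0.0, 0.0]])
        assert cross_entropy(probs, y) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_costs_log3(self):
        probs = np.full((4, 3), 1.0 / 3.0)
        y = np.eye(3)[[0, 1, 2, 0]]
        assert cross_entropy(probs, y) == pytest.approx(np.log(3), abs=1e-9)


class TestBackprop:
    def test_analytic_gradients_match_finite_differences(self):
        rng = np.random.default_rng(7)
        model = ClassifierModel(seed=0)
        X = rng.normal(size=(4, 2, 9, 9))
        Y = np.eye(3)[rng.integers(0, 3, 4)]

        def loss():
            probs, _ = model.forward(X)
            return -(Y * np.log(probs + 1e-12)).sum()

        probs, cache = model.forward(X)
        grads = model.backward(cache, Y)
        eps = 1e-6
        for name in ("W1", "b1", "W2", "W3", "b3", "W4", "b4"):
            p = model.params[name]
            flat = p.reshape(-1)
            for idx in rng.choice(flat.size, size=min(4, flat.size),
                                  replace=False):
                old = flat[idx]
                flat[idx] = old + eps
                lp = loss()
                flat[idx] = old - eps
                lm = loss()
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[name].reshape(-1)[idx]
                assert ana == pytest.approx(num, rel=1e-4, abs=1e-6), name


class TestTraining:
    def test_learning_rate_schedule(self):
        cfg = TrainConfig()
        assert cfg.learning_rate(1) == 0.025
        assert cfg.learning_rate(15) == 0.025
        assert cfg.learning_rate(16) == 0.005
        assert cfg.learning_rate(30) == 0.005

    def test_invalid_configs_rejected(self):
        with pytest.raises(ParameterError):
            TrainConfig(batch_size=0)
        with pytest.raises(ParameterError):
            TrainConfig(dropout_fc=1.0)
        with pytest.raises(ParameterError):
            TrainConfig(validation_fraction=0.0)

    def test_short_training_is_seeded_and_loss_finite(self):
        ds = generate_labeled_rois(12, (8.0,), seed=9)
        cfg = TrainConfig(epochs=2, seed=5)
        m1, log1 = train(ds, cfg)
        m2, log2 = train(ds, cfg)
        assert np.isfinite(log1[["train_loss", "val_loss"]].to_numpy()).all()
        assert list(log1.columns) == [
            "epoch", "lr", "train_loss", "train_acc", "val_loss", "val_acc"
        ]
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])

    def test_empty_dataset_rejected(self):
        with pytest.raises(ParameterError):
            train(LabeledDataset(patches=np.zeros((0, 9, 9)), labels=[]),
                  TrainConfig(epochs=1))

    def test_missing_class_warns(self):
        ds = generate_labeled_rois(8, (None,), seed=1)
        keep = ds.labels != 2
        with pytest.warns(UserWarning):
            train(ds.subset(np.nonzero(keep)[0]), TrainConfig(epochs=1, seed=0))


class TestTrainedModel:
    def test_validation_accuracy_exceeds_90_percent(self, trained_model):
        assert trained_model.training_log["val_acc"].iloc[-1] > 0.9

    def test_probabilities_sum_to_one(self, trained_model, test_dataset):
        probs, _ = predict(trained_model, test_dataset)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert (probs >= 0).all()

    def test_inference_is_deterministic(self, trained_model):
        patch = ideal_patch(0.5)[None, :, :]
        p1, _ = predict(trained_model, patch)
        p2, _ = predict(trained_model, patch)
        assert np.array_equal(p1, p2)

    def test_ideal_patches_classified_correctly(self, trained_model):
        for charge, label in ((0.5, "+1/2"), (-0.5, "-1/2")):
            for phase in (0.0, 0.7, 2.1):
                _, labels = predict(
                    trained_model, ideal_patch(charge, phase=phase)[None]
                )
                assert labels[0] == label

    def test_shape_mismatch_rejected(self, trained_model):
        with pytest.raises(ParameterError):
            predict(trained_model, np.zeros((1, 7, 7)))

    def test_save_load_round_trip(self, trained_model, test_dataset, tmp_path):
        path = tmp_path / "model.npz"
        trained_model.save(path)
        clone = ClassifierModel.load(path)
        assert clone.class_order == CLASSES
        p0, _ = predict(trained_model, test_dataset)
        p1, _ = predict(clone, test_dataset)
        assert np.allclose(p0, p1)
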