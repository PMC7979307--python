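"""Loss function, gradient identity, and training-loop contracts."""

import warnings

import numpy as np
import pytest

import nodulecam as nc
from nodulecam import nn
from nodulecam.training import (
    ClassifierResults,
    NoduleClassifier,
    TrainConfig,
    cross_entropy_loss,
    softmax,
)


def tiny_description(edge=7):
    """A minute 3D CNN sharing the real model's layer vocabulary."""
    return nc.NetworkDescription(
        name="proposed3d",
        input_shape=(1, edge, edge, edge),
        layers=[
            nc.LayerSpec(kind="conv3d", in_channels=1, out_channels=4,
                         kernel=3, padding="same", activation="relu"),
            nc.LayerSpec(kind="batchnorm", in_channels=4, out_channels=4),
            nc.LayerSpec(kind="maxpool3d", kernel=7),
            nc.LayerSpec(kind="flatten"),
            nc.LayerSpec(kind="dense", in_channels=4, out_channels=2),
        ],
    )


def tiny_samples(n, edge=7, seed=0):
    config = nc.PhantomConfig(
        edge=edge, nodule_radius_range=(1.0, 1.5), noise_sd=0.0,
        vessel_count_range=(0, 1),
    )
    return nc.generate_dataset(config, n // 2, n - n // 2, seed=seed)


class TestCrossEntropy:
    def test_uniform_scores_give_ln2(self):
        assert cross_entropy_loss(np.zeros((4, 2)), [0, 1, 0, 1]) == (
            pytest.approx(np.log(2))
        )

    def test_extreme_scores_are_stable(self):
        loss = cross_entropy_loss(np.array([[1000.0, -1000.0]]), [0])
        assert loss == pytest.approx(0.0, abs=1e-12)
        loss = cross_entropy_loss(np.array([[1000.0, -1000.0]]), [1])
        assert np.isfinite(loss) and loss > 100

    def test_direct_evaluation(self):
        loss = cross_entropy_loss(np.array([[1.0, 2.0]]), [1])
        assert loss == pytest.approx(0.31326168751822286, abs=1e-12)

    def test_bad_label_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy_loss(np.zeros((1, 2)), [2])

    @pytest.mark.parametrize("seed", range(3))
    def test_analytic_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=(6, 2)) * 3
        labels = rng.integers(0, 2, 6)
        _, grad = cross_entropy_loss(scores, labels, return_grad=True)
        eps = 1e-6
        for i in range(6):
            for j in range(2):
                s = scores.copy()
                s[i, j] += eps
                f1 = cross_entropy_loss(s, labels)
                s[i, j] -= 2 * eps
                f2 = cross_entropy_loss(s, labels)
                assert abs((f1 - f2) / (2 * eps) - grad[i, j]) < 1e-4
        # the analytic form is softmax minus one-hot over batch size
        expected = softmax(scores)
        expected[np.arange(6), labels] -= 1
        np.testing.assert_allclose(grad, expected / 6, atol=1e-12)


class TestFitContracts:
    def make_classifier(self, n=12, **kwargs):
        samples = tiny_samples(n)
        labels = np.array([s.label for s in samples])
        manifest = nc.make_splits(labels, 0.7, 0.25, seed=0)
        return NoduleClassifier.from_samples(
            samples, manifest, description=tiny_description(), **kwargs
        )

    def test_single_epoch_history(self):
        clf = self.make_classifier()
        res = clf.fit(TrainConfig(epochs=1, batch_size=4, seed=0))
        assert res.history.n_epochs == 1
        assert len(res.history.val_loss) == 1

    def test_zero_learning_rate_is_identity(self):
        clf = self.make_classifier()
        res = clf.fit(TrainConfig(epochs=2, learning_rate=0.0, seed=3,
                                  early_stop_patience=None))
        fresh = nc.build_model(clf.description, seed=3)
        trained = res.handle.net.state()
        for key, value in fresh.net.state().items():
            if "running" in key:  # batchnorm statistics still update
                continue
            np.testing.assert_array_equal(trained[key], value)

    def test_fixed_seed_reproduces_history(self):
        cfg = TrainConfig(epochs=2, batch_size=4, seed=11)
        a = self.make_classifier().fit(cfg).history
        b = self.make_classifier().fit(cfg).history
        assert a.train_loss == b.train_loss
        assert a.val_loss == b.val_loss

    def test_best_epoch_is_earliest_minimum(self):
        h = nc.TrainHistory(train_loss=[3, 2, 1], val_loss=[2.0, 1.0, 1.0],
                            val_accuracy=[0.5, 0.6, 0.6])
        assert h.best_epoch == 1

    def test_shape_mismatch_detected_before_training(self):
        samples = tiny_samples(8, edge=7)
        labels = np.array([s.label for s in samples])
        with pytest.raises(ValueError, match="does not match"):
            NoduleClassifier(labels, [s.volume for s in samples],
                             description=tiny_description(edge=9))

    def test_summary_mentions_architecture_and_epochs(self):
        clf = self.make_classifier()
        res = clf.fit(TrainConfig(epochs=1, batch_size=4, seed=0))
        text = res.summary()
        assert "proposed3d" in text
        assert "best epoch" in text


class TestPredict:
    def make_results(self):
        clf = TestFitContracts().make_classifier()
        return clf.fit(TrainConfig(epochs=1, batch_size=4, seed=0))

    def test_zeroed_final_layer_gives_half(self):
        res = self.make_results()
        final = res.handle.net.layers[-1]
        final.params["w"][:] = 0.0
        final.params["b"][:] = 0.0
        samples = tiny_samples(4, seed=9)
        probs = res.predict(samples)
        np.testing.assert_allclose(probs, 0.5, atol=1e-12)

    def test_probabilities_complementary_and_ordered(self):
        res = self.make_results()
        samples = tiny_samples(6, seed=10)
        both = res.predict_proba(samples)
        np.testing.assert_allclose(both.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(both[:, 1], res.predict(samples), atol=1e-12)
        assert ((both >= 0) & (both <= 1)).all()


class TestSingleUseTestSet:
    def test_second_test_evaluation_warns(self):
        res = TestPredict().make_results()
        samples = tiny_samples(6, seed=12)
        labels = [s.label for s in samples]
        manifest = object()
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            res.evaluate_test(samples, labels, manifest)
            res.validate()  # validation stays repeatable
            res.validate()
        with pytest.warns(UserWarning, match="more than once"):
            res.evaluate_test(samples, labels, manifest)

    def test_validate_does_not_warn(self):
        res = TestPredict().make_results()
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            res.validate()
            res.validate()


def test_loss_decreases_on_easy_phantoms_median_over_seeds():
    """Cross-entropy falls over the first epochs of the separable task."""
    drops = []
    for seed in range(3):
        samples = tiny_samples(16, seed=seed)
        labels = np.array([s.label for s in samples])
        manifest = nc.make_splits(labels, 0.75, 0.2, seed=seed)
        clf = NoduleClassifier.from_samples(
            samples, manifest, description=tiny_description(), init="he"
        )
        res = clf.fit(TrainConfig(epochs=4, batch_size=4, seed=seed,
                                  learning_rate=0.01,
                                  early_stop_patience=None))
        drops.append(res.history.train_loss[-1] - res.history.train_loss[0])
    assert np.median(drops) < 0
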