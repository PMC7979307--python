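"""Grad-CAM correctness: GAP/weight oracles, CAM equivalence, invariances."""

import numpy as np
import pytest

from nodulecam import nn
from nodulecam.gradcam import (
    GradCamContext,
    ToyModel,
    cam_from_gap_classifier,
    class_weights,
    global_average_pool,
    grad_cam,
    minmax_normalize,
    overlay,
)

from conftest import make_gap_toy


class TestGlobalAveragePool:
    def test_constant_map(self):
        maps = np.full((2, 3, 3, 3), 5.0)
        np.testing.assert_allclose(global_average_pool(maps), [5.0, 5.0])

    def test_arithmetic_mean_oracle(self):
        maps = np.arange(8, dtype=float).reshape(1, 2, 2, 2)
        assert global_average_pool(maps)[0] == pytest.approx(3.5)

    def test_zero_map(self):
        assert global_average_pool(np.zeros((1, 4, 4)))[0] == 0.0

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            global_average_pool(np.zeros((2, 0, 3)))


class TestClassWeights:
    def test_zero_gradients(self):
        np.testing.assert_array_equal(
            class_weights(np.zeros((3, 4, 4))), np.zeros(3)
        )

    def test_paired_cancellation(self):
        grads = np.stack([np.array([[1.0, -1.0], [-1.0, 1.0]])])
        assert class_weights(grads)[0] == 0.0

    def test_summation_oracle(self):
        grads = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        assert class_weights(grads)[0] == 10.0


class TestContextInvariants:
    def test_gap_values_match_mean(self, rng):
        acts = rng.normal(size=(3, 4, 4, 4))
        ctx = GradCamContext(acts, rng.normal(size=acts.shape))
        np.testing.assert_allclose(
            ctx.gap_values, acts.mean(axis=(1, 2, 3)), atol=1e-6
        )
        assert ctx.spatial_size == 64

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            GradCamContext(rng.normal(size=(2, 3, 3)),
                           rng.normal(size=(2, 4, 4)))


class TestGradCam:
    @pytest.mark.parametrize("ndim", [2, 3])
    def test_cam_equivalence_on_gap_networks(self, ndim, rng):
        """On conv->GAP->linear networks, Grad-CAM must reduce to CAM."""
        for seed in range(3):
            model = make_gap_toy(ndim=ndim, seed=seed)
            x = rng.normal(size=(6,) * ndim)
            for class_index in (0, 1):
                hm = grad_cam(model, x, class_index)
                cam = cam_from_gap_classifier(model, x, class_index)
                np.testing.assert_allclose(hm.normalized, cam, atol=1e-5)

    def test_constant_score_yields_zero_heatmap(self, rng):
        model = make_gap_toy(seed=0)
        # zero the classifier: class scores no longer depend on the input
        model.net.layers[-1].params["w"][:] = 0.0
        hm = grad_cam(model, rng.normal(size=(6, 6, 6)))
        np.testing.assert_array_equal(hm.values, 0.0)
        np.testing.assert_array_equal(hm.upsampled, 0.0)

    def test_heatmaps_non_negative_everywhere(self, rng):
        model = make_gap_toy(seed=1)
        for _ in range(5):
            hm = grad_cam(model, rng.normal(size=(6, 6, 6)))
            assert (hm.values >= 0).all()
            assert (hm.upsampled >= 0).all()

    def test_single_map_proportionality(self, rng):
        """With one feature map and a positive weight, the heatmap is the
        (rectified) activation map up to scale."""
        model = make_gap_toy(n_maps=1, seed=2, conv_relu=True)
        model.net.layers[-1].params["w"][0, 1] = 1.0  # positive class weight
        x = rng.normal(size=(6, 6, 6))
        hm, ctx = grad_cam(model, x, class_index=1, return_context=True)
        acts = ctx.activations[0]
        assert ctx.weights[0] > 0
        np.testing.assert_allclose(
            hm.normalized, minmax_normalize(acts), atol=1e-10
        )

    def test_recomputation_is_bit_identical(self, rng):
        model = make_gap_toy(seed=3)
        x = rng.normal(size=(6, 6, 6))
        a = grad_cam(model, x)
        b = grad_cam(model, x)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.upsampled, b.upsampled)

    def test_scale_covariance_of_normalized_heatmap(self, rng):
        """Scaling target activations while compensating downstream leaves
        the class score and the normalized heatmap unchanged."""
        scale = 7.5
        x = rng.normal(size=(6, 6, 6))
        base = make_gap_toy(seed=4, conv_relu=True)
        scaled = make_gap_toy(seed=4, conv_relu=True)
        conv = scaled.net.layers[0]
        conv.params["w"] *= scale
        conv.params["b"] *= scale
        scaled.net.layers[-1].params["w"] /= scale
        s_base = base.net.forward(np.asarray(x)[None, None])
        s_scaled = scaled.net.forward(np.asarray(x)[None, None])
        np.testing.assert_allclose(s_base, s_scaled, atol=1e-8)
        hm_base = grad_cam(base, x)
        hm_scaled = grad_cam(scaled, x)
        np.testing.assert_allclose(
            hm_base.normalized, hm_scaled.normalized, atol=1e-5
        )

    def test_sum_vs_mean_weight_convention_indifference(self, rng):
        """Dividing the gradient sum by the number of positions rescales
        every map weight equally; normalized heatmaps cannot change."""
        model = make_gap_toy(seed=5)
        x = rng.normal(size=(6, 6, 6))
        hm, ctx = grad_cam(model, x, return_context=True)
        z = ctx.spatial_size
        raw_mean = np.maximum(
            np.tensordot(ctx.weights / z, ctx.activations, axes=(0, 0)), 0.0
        )
        np.testing.assert_allclose(hm.values, raw_mean * z, atol=1e-8)
        np.testing.assert_allclose(
            hm.normalized, minmax_normalize(raw_mean), atol=1e-12
        )

    def test_class_index_out_of_range(self, rng):
        model = make_gap_toy(seed=0)
        with pytest.raises(ValueError, match="class_index"):
            grad_cam(model, rng.normal(size=(6, 6, 6)), class_index=2)

    def test_upsampling_to_input_resolution(self, rng):
        r = np.random.default_rng(11)
        net = nn.Sequential(
            [
                nn.Conv(3, 1, 2, 3, "same", rng=r, init="he", dtype=np.float64),
                nn.MaxPool(3, 2),
                nn.Conv(3, 2, 2, 2, "valid", rng=r, init="he", dtype=np.float64),
                nn.Flatten(),
                nn.Dense(2 * 27, 2, rng=r, init="he", dtype=np.float64),
            ]
        )
        model = ToyModel(net=net, input_shape=(1, 8, 8, 8))
        hm = grad_cam(model, rng.normal(size=(8, 8, 8)))
        assert hm.values.shape == (3, 3, 3)
        assert hm.upsampled.shape == (8, 8, 8)
        if hm.values.max() > 0:
            assert hm.upsampled.max() == pytest.approx(1.0)


class TestOverlay:
    def _volume_and_map(self, rng, zero=False):
        vol = rng.normal(size=(9, 9, 9))
        h = np.zeros((9, 9, 9)) if zero else rng.random((9, 9, 9))
        return vol, h

    def test_zero_heatmap_returns_grayscale(self, rng):
        vol, h = self._volume_and_map(rng, zero=True)
        out = overlay(vol, h, slice_axis=0, slice_index=4)
        gray = minmax_normalize(vol[4])
        for ch in range(3):
            np.testing.assert_allclose(out[..., ch], gray, atol=1e-12)

    def test_saturated_heatmap_alpha_one_is_pure_colormap(self, rng):
        import matplotlib

        vol, _ = self._volume_and_map(rng)
        h = np.ones((9, 9, 9))
        out = overlay(vol, h, slice_axis=1, slice_index=0, alpha=1.0)
        expected = matplotlib.colormaps["jet"](np.ones((9, 9)))[..., :3]
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_out_of_bounds_slice_rejected(self, rng):
        vol, h = self._volume_and_map(rng)
        with pytest.raises(IndexError):
            overlay(vol, h, slice_axis=2, slice_index=9)

    def test_resolution_mismatch_rejected(self, rng):
        vol = rng.normal(size=(9, 9, 9))
        with pytest.raises(ValueError):
            overlay(vol, np.zeros((3, 3, 3)))
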