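"""Gradient-weighted class activation mapping for planar and volumetric CNNs.

Grad-CAM localizes the evidence a classifier uses for one class: the
feature maps :math:`A^k` of a chosen convolutional layer are combined with
weights :math:`\\alpha_k^c` equal to the (spatially summed) gradient of the
pre-softmax class score :math:`y^c` with respect to each map, and the
weighted sum is rectified,

.. math:: L^c = \\mathrm{ReLU}\\Big(\\sum_k \\alpha_k^c A^k\\Big).

For a network ending in global average pooling followed by a single linear
classifier, these gradient weights reduce exactly to the classifier's
weights, i.e. Grad-CAM degenerates to classical CAM — a property the test
suite exploits as a correctness oracle.

Weights use the unnormalized spatial sum of gradients; dividing by the
number of spatial positions ``z`` (the mean convention) rescales every map
by the same constant and is therefore invisible after min-max
normalization, which this module always applies to reported heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .architectures import ModelHandle
from . import nn

__all__ = [
    "GradCamContext",
    "Heatmap",
    "global_average_pool",
    "class_weights",
    "grad_cam",
    "minmax_normalize",
    "overlay",
]


def global_average_pool(activations: np.ndarray) -> np.ndarray:
    """Spatial mean of each feature map: (C, *S) -> (C,).

    The first axis indexes maps; all remaining axes are spatial.
    """
    activations = np.asarray(activations)
    if activations.ndim < 2 or activations[0].size == 0:
        raise ValueError("each feature map needs at least one spatial position")
    return activations.mean(axis=tuple(range(1, activations.ndim)))


def class_weights(gradients: np.ndarray) -> np.ndarray:
    """Per-map Grad-CAM weights: the spatial sum of class-score gradients."""
    gradients = np.asarray(gradients)
    if gradients.ndim < 2:
        raise ValueError("gradients must have shape (maps, *spatial)")
    return gradients.sum(axis=tuple(range(1, gradients.ndim)))


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Affine rescale to [0, 1]; a constant array maps to all zeros."""
    lo = float(values.min())
    hi = float(values.max())
    if hi <= lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


@dataclass
class Heatmap:
    """Saliency on the target layer grid and resampled to input resolution.

    ``values`` is the raw rectified weighted sum on the conv layer's grid;
    ``upsampled`` is its trilinear (bilinear in 2D) resampling to the input
    volume extent, min-max normalized to [0, 1].
    """

    values: np.ndarray
    upsampled: np.ndarray
    normalization: str = "minmax"

    @property
    def normalized(self) -> np.ndarray:
        return minmax_normalize(self.values)


@dataclass
class GradCamContext:
    """Everything Grad-CAM touches, kept for inspection and testing."""

    activations: np.ndarray          # (maps, *spatial) at the target layer
    gradients: np.ndarray            # d y^c / d activations, same shape
    gap_values: np.ndarray = field(init=False)
    weights: np.ndarray = field(init=False)
    class_scores: np.ndarray | None = None
    class_index: int = 0
    target_layer: str = ""
    heatmap: Heatmap | None = None

    def __post_init__(self) -> None:
        if self.activations.shape != self.gradients.shape:
            raise ValueError("activations and gradients must share a shape")
        self.gap_values = global_average_pool(self.activations)
        self.weights = class_weights(self.gradients)

    @property
    def spatial_size(self) -> int:
        return int(np.prod(self.activations.shape[1:]))


@dataclass
class ToyModel:
    """Minimal handle wrapping a bare :class:`nodulecam.nn.Sequential`,
    mainly for small hand-built networks in tests and demonstrations."""

    net: nn.Sequential
    input_shape: tuple[int, ...]
    dtype: type = np.float64


def _conv_indices(net: nn.Sequential) -> list[int]:
    return [i for i, l in enumerate(net.layers) if isinstance(l, nn.Conv)]


def _feature_grid_affine(net: nn.Sequential, idx: int) -> tuple[float, float]:
    """Affine map from target-layer cell index to input voxel coordinate.

    Cell ``i`` of the target layer is centered on input coordinate
    ``start + jump * i`` (isotropic: all layers here use cubic kernels).
    Standard receptive-field arithmetic: a convolution with kernel k and
    leading padding p shifts the centers by ((k-1)/2 - p) current jumps; a
    pooling layer with window k shifts by (k-1)/2 and multiplies the jump.
    Valid-padded convolutions make this offset substantial, so a plain
    proportional zoom would misplace the map by several voxels.
    """
    jump = 1.0
    start = 0.0
    for layer in net.layers[: idx + 1]:
        if isinstance(layer, nn.Conv):
            pb, _ = nn._pad_amounts(layer.kernel, layer.padding)
            start += ((layer.kernel - 1) / 2 - pb) * jump
        elif isinstance(layer, nn.MaxPool):
            start += (layer.kernel - 1) / 2 * jump
            jump *= layer.kernel
    return jump, start


def _upsample_aligned(
    raw: np.ndarray,
    net: nn.Sequential,
    idx: int,
    in_spatial: tuple[int, ...],
) -> np.ndarray:
    """Resample a target-grid map to input resolution along the true
    receptive-field geometry (linear interpolation, edge clamped)."""
    jump, start = _feature_grid_affine(net, idx)
    axes = [(np.arange(s, dtype=np.float64) - start) / jump for s in in_spatial]
    coords = np.stack(np.meshgrid(*axes, indexing="ij"))
    return ndimage.map_coordinates(raw, coords, order=1, mode="nearest")


def _resolve_target(model, target_layer: str | int | None) -> int:
    conv_idx = _conv_indices(model.net)
    if not conv_idx:
        raise ValueError("model has no convolutional layer to target")
    if target_layer is None:
        return conv_idx[-1]
    if isinstance(target_layer, int):
        idx = target_layer
    else:
        idx = next(
            (i for i, l in enumerate(model.net.layers) if l.name == target_layer),
            None,
        )
        if idx is None:
            raise KeyError(f"no layer named {target_layer!r}")
    if idx not in conv_idx:
        raise ValueError(
            f"target layer {target_layer!r} is not a convolutional layer"
        )
    return idx


def grad_cam(
    model: ModelHandle,
    volume: np.ndarray,
    class_index: int = 1,
    target_layer: str | int | None = None,
    return_context: bool = False,
):
    """Heatmap of class evidence for one input volume.

    The gradient is taken on the pre-softmax class score.  The network is
    run in inference mode (dropout off, batch-norm running statistics), so
    repeated calls with the same inputs are bit-identical.

    Parameters
    ----------
    model : ModelHandle
        A built (optionally trained) network.
    volume : ndarray
        A single input of shape ``(channels, *spatial)`` matching the
        model's declared input shape, or ``(*spatial)`` for single-channel.
    class_index : int
        Which of the two class scores to explain (default: nodule = 1).
    target_layer : str | int | None
        Conv layer to read activations from; defaults to the last one.
    """
    volume = np.asarray(volume, dtype=model.dtype)
    if volume.ndim == len(model.input_shape) - 1:
        volume = volume[None]
    if volume.shape != tuple(model.input_shape):
        raise ValueError(
            f"volume shape {volume.shape} != model input {model.input_shape}"
        )
    idx = _resolve_target(model, target_layer)

    outputs = model.net.forward_cached(volume[None], training=False)
    scores = outputs[-1]
    n_classes = scores.shape[1]
    if not 0 <= class_index < n_classes:
        raise ValueError(f"class_index {class_index} out of range 0..{n_classes - 1}")
    dscores = np.zeros_like(scores)
    dscores[0, class_index] = 1.0
    model.net.zero_grad()
    grad = model.net.grad_at_layer(idx, dscores)

    acts = outputs[idx][0].astype(np.float64)
    grads = grad[0].astype(np.float64)
    ctx = GradCamContext(
        activations=acts,
        gradients=grads,
        class_scores=scores[0],
        class_index=class_index,
        target_layer=model.net.layers[idx].name,
    )
    raw = np.maximum(np.tensordot(ctx.weights, acts, axes=(0, 0)), 0.0)
    in_spatial = model.input_shape[1:]
    up = _upsample_aligned(raw, model.net, idx, in_spatial)
    heatmap = Heatmap(values=raw, upsampled=minmax_normalize(up))
    ctx.heatmap = heatmap
    if return_context:
        return heatmap, ctx
    return heatmap


def cam_from_gap_classifier(model, volume: np.ndarray,
                            class_index: int = 1) -> np.ndarray:
    """Classical CAM for a conv -> GAP -> dense network, from the dense
    weights directly (no gradients); returns the min-max normalized map on
    the conv grid.  Used as the analytic cross-check for :func:`grad_cam`.
    """
    volume = np.asarray(volume, dtype=model.dtype)
    if volume.ndim == len(model.input_shape) - 1:
        volume = volume[None]
    conv_idx = _conv_indices(model.net)[-1]
    outputs = model.net.forward_cached(volume[None], training=False)
    acts = outputs[conv_idx][0].astype(np.float64)
    dense = next(
        l for l in model.net.layers if isinstance(l, nn.Dense)
    )
    w = dense.params["w"][:, class_index].astype(np.float64)
    cam = np.maximum(np.tensordot(w, acts, axes=(0, 0)), 0.0)
    return minmax_normalize(cam)


def overlay(
    volume: np.ndarray,
    heatmap: Heatmap | np.ndarray,
    slice_axis: int = 0,
    slice_index: int | None = None,
    alpha: float = 0.5,
    cmap: str = "jet",
) -> np.ndarray:
    """Blend a grayscale volume slice with a color-mapped saliency slice.

    Per-pixel blending weight is ``alpha * h`` with ``h`` the normalized
    saliency, so regions the model ignores stay untouched grayscale and a
    saturated map at ``alpha=1`` yields the pure colormap.  Returns an
    (H, W, 3) float RGB array in [0, 1].
    """
    import matplotlib

    volume = np.asarray(volume)
    hvals = heatmap.upsampled if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    if hvals.shape != volume.shape:
        raise ValueError("heatmap must be upsampled to the volume resolution")
    if slice_index is None:
        slice_index = volume.shape[slice_axis] // 2
    if not 0 <= slice_index < volume.shape[slice_axis]:
        raise IndexError(
            f"slice index {slice_index} out of bounds for axis {slice_axis} "
            f"with size {volume.shape[slice_axis]}"
        )
    gray2d = minmax_normalize(np.take(volume, slice_index, axis=slice_axis))
    h2d = np.clip(np.take(hvals, slice_index, axis=slice_axis), 0.0, 1.0)
    colors = matplotlib.colormaps[cmap](h2d)[..., :3]
    gray_rgb = np.repeat(gray2d[..., None], 3, axis=-1)
    w = (alpha * h2d)[..., None]
    return (1.0 - w) * gray_rgb + w * colors
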