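"""Minimal NumPy neural-network engine for small volumetric CNNs.

Implements exactly the layer vocabulary needed by the nodule classifier —
N-dimensional convolution (stride 1, same/valid padding), batch
normalization, non-overlapping max pooling, flatten, dense, dropout and
global average pooling — with hand-written backward passes so that
gradients with respect to intermediate feature maps are available for
class-activation mapping.

Convolutions are evaluated as an accumulation of one GEMM per kernel
offset (a shift-and-multiply decomposition of cross-correlation): for each
of the kernel^nd offsets, a contiguous shifted view of the padded input is
multiplied by the corresponding kernel slice through BLAS.  This keeps the
peak memory footprint at one volume copy instead of the kernel^nd-fold
blow-up of an im2col matrix, which matters for 27-voxel cubes.

All randomness (weight initialization, dropout masks, batch shuffling at
the training level) flows through ``numpy.random.Generator`` objects seeded
explicitly, so a build or a training run is bit-reproducible.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np

__all__ = [
    "Layer",
    "Conv",
    "BatchNorm",
    "MaxPool",
    "GlobalAveragePool",
    "Flatten",
    "Dense",
    "Dropout",
    "Sequential",
    "Adam",
]


def _pad_amounts(kernel: int, padding: str) -> tuple[int, int]:
    """Per-axis (before, after) zero padding for stride-1 convolution.

    ``same`` distributes kernel-1 with the extra voxel trailing, matching
    the convention under which an even kernel preserves the input extent.
    """
    if padding == "same":
        return ((kernel - 1) // 2, kernel // 2)
    if padding == "valid":
        return (0, 0)
    raise ValueError(f"unknown padding mode {padding!r}")


class Layer:
    """Base class: forward caches whatever backward needs; backward
    accumulates parameter gradients in ``grads`` and returns the input
    gradient."""

    name: str = ""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_count(self) -> int:
        """Stored parameters, including non-trainable statistics."""
        return int(sum(p.size for p in self.params.values()))

    def trainable(self) -> Sequence[str]:
        return tuple(self.params)

    def zero_grad(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}


class Conv(Layer):
    """N-dimensional cross-correlation with cubic kernel, stride 1,
    optional fused ReLU."""

    def __init__(
        self,
        ndim: int,
        in_channels: int,
        out_channels: int,
        kernel: int,
        padding: str = "valid",
        relu: bool = True,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        init: str = "uniform",
        dtype=np.float32,
    ) -> None:
        super().__init__()
        if ndim not in (2, 3):
            raise ValueError("ndim must be 2 or 3")
        self.ndim = ndim
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.padding = padding
        self.relu = relu
        self.use_bias = bias
        rng = rng or np.random.default_rng(0)
        shape = (out_channels, in_channels) + (kernel,) * ndim
        fan_in = in_channels * kernel**ndim
        if init == "uniform":
            w = rng.uniform(-1.0, 1.0, size=shape)
        elif init == "he":
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
        else:
            raise ValueError(f"unknown init {init!r}")
        self.params["w"] = w.astype(dtype)
        if bias:
            self.params["b"] = np.zeros(out_channels, dtype=dtype)
        self.zero_grad()

    def out_spatial(self, spatial: tuple[int, ...]) -> tuple[int, ...]:
        pb, pa = _pad_amounts(self.kernel, self.padding)
        out = tuple(s + pb + pa - self.kernel + 1 for s in spatial)
        if any(s < 1 for s in out):
            raise ValueError(
                f"{self.name or 'conv'}: spatial extent {spatial} collapses "
                f"below 1 under kernel {self.kernel} / {self.padding} padding"
            )
        return out

    def _offsets(self):
        return itertools.product(range(self.kernel), repeat=self.ndim)

    @property
    def _wide(self) -> bool:
        # with few input channels the per-offset GEMMs degenerate to thin
        # outer products; an unrolled im2col matrix is faster there
        return self.in_channels >= 8

    def _im2col(self, xp: np.ndarray, out_sp: tuple[int, ...]) -> np.ndarray:
        n, c = xp.shape[:2]
        k_elems = self.kernel**self.ndim
        cols = np.empty((n, c, k_elems) + out_sp, dtype=xp.dtype)
        for flat, off in enumerate(self._offsets()):
            sl = tuple(slice(o, o + s) for o, s in zip(off, out_sp))
            cols[:, :, flat] = xp[(slice(None), slice(None)) + sl]
        return cols.reshape(n, c * k_elems, int(np.prod(out_sp)))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        spatial = x.shape[2:]
        out_sp = self.out_spatial(spatial)
        pb, pa = _pad_amounts(self.kernel, self.padding)
        pad = ((0, 0), (0, 0)) + ((pb, pa),) * self.ndim
        xp = np.pad(x, pad)
        n, c = x.shape[:2]
        p = int(np.prod(out_sp))
        if self._wide:
            # accumulate one GEMM per kernel offset; avoids materializing
            # the k^nd-times-larger im2col matrix
            w2 = self.params["w"].reshape(self.out_channels, c, -1)
            y = np.zeros((n, self.out_channels, p), dtype=x.dtype)
            for flat, off in enumerate(self._offsets()):
                sl = tuple(slice(o, o + s) for o, s in zip(off, out_sp))
                xoff = np.ascontiguousarray(
                    xp[(slice(None), slice(None)) + sl]
                ).reshape(n, c, p)
                y += np.matmul(w2[:, :, flat], xoff)
        else:
            cols = self._im2col(xp, out_sp)
            y = np.matmul(self.params["w"].reshape(self.out_channels, -1), cols)
        if self.use_bias:
            y += self.params["b"][None, :, None]
        y = y.reshape((n, self.out_channels) + out_sp)
        if self.relu:
            y = np.maximum(y, 0.0)
        self._cache = (xp, spatial, out_sp, y if self.relu else None)
        return y

    def _backward_wide(self, dy2, xp, out_sp, need_input_grad=True):
        n = dy2.shape[0]
        c = self.in_channels
        p = int(np.prod(out_sp))
        w2 = self.params["w"].reshape(self.out_channels, c, -1)
        dw2 = np.zeros_like(w2)
        dxp = np.zeros_like(xp) if need_input_grad else None
        out_shape = (n, c) + out_sp
        for flat, off in enumerate(self._offsets()):
            sl = (slice(None), slice(None)) + tuple(
                slice(o, o + s) for o, s in zip(off, out_sp)
            )
            xoff = np.ascontiguousarray(xp[sl]).reshape(n, c, p)
            # batched GEMM over the sample axis; the transposed view of a
            # contiguous xoff is BLAS-friendly and needs no copy
            dw2[:, :, flat] = np.matmul(dy2, xoff.transpose(0, 2, 1)).sum(0)
            if need_input_grad:
                dxp[sl] += np.matmul(w2[:, :, flat].T, dy2).reshape(out_shape)
        self.grads["w"] += dw2.reshape(self.params["w"].shape)
        return dxp

    def _backward_narrow(self, dy2, xp, out_sp, need_input_grad=True):
        # one big im2col GEMM for the weight gradient; thin-channel layers
        # make the per-offset GEMMs above degenerate
        n = dy2.shape[0]
        c = self.in_channels
        cols = self._im2col(xp, out_sp)
        dw2 = np.matmul(dy2, cols.transpose(0, 2, 1)).sum(0)
        self.grads["w"] += dw2.reshape(self.params["w"].shape)
        if not need_input_grad:
            return None
        # input gradient via one GEMM into column space, then scatter-add
        w2 = self.params["w"].reshape(self.out_channels, -1)
        dcols = np.matmul(w2.T, dy2)  # (n, c*k^nd, positions)
        k_elems = self.kernel**self.ndim
        dcols = dcols.reshape((n, c, k_elems) + out_sp)
        dxp = np.zeros_like(xp)
        for flat, off in enumerate(self._offsets()):
            sl = (slice(None), slice(None)) + tuple(
                slice(o, o + s) for o, s in zip(off, out_sp)
            )
            dxp[sl] += dcols[:, :, flat]
        return dxp

    def backward(self, dy: np.ndarray, need_input_grad: bool = True) -> np.ndarray:
        xp, spatial, out_sp, post = self._cache
        if self.relu:
            dy = np.where(post > 0, dy, 0.0)
        n = dy.shape[0]
        p = int(np.prod(out_sp))
        dy2 = np.ascontiguousarray(dy.reshape(n, self.out_channels, p))
        if self.use_bias:
            self.grads["b"] += dy2.sum(axis=(0, 2))
        if self._wide:
            dxp = self._backward_wide(dy2, xp, out_sp, need_input_grad)
        else:
            dxp = self._backward_narrow(dy2, xp, out_sp, need_input_grad)
        if not need_input_grad:
            return None
        pb, pa = _pad_amounts(self.kernel, self.padding)
        if pb or pa:
            sl = (slice(None), slice(None)) + tuple(
                slice(pb, pb + s) for s in spatial
            )
            dxp = dxp[sl]
        return dxp


class BatchNorm(Layer):
    """Per-channel normalization over batch and spatial axes.

    Stores four parameter vectors per channel (scale, shift, running mean,
    running variance); only scale and shift receive gradients.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9,
                 dtype=np.float32) -> None:
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        self.params["running_mean"] = np.zeros(channels, dtype=dtype)
        self.params["running_var"] = np.ones(channels, dtype=dtype)
        self.zero_grad()

    def trainable(self) -> Sequence[str]:
        return ("gamma", "beta")

    def _bshape(self, ndim: int) -> tuple[int, ...]:
        return (1, self.channels) + (1,) * (ndim - 2)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = (0,) + tuple(range(2, x.ndim))
        bs = self._bshape(x.ndim)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.params["running_mean"] = (
                m * self.params["running_mean"] + (1 - m) * mean
            ).astype(x.dtype)
            self.params["running_var"] = (
                m * self.params["running_var"] + (1 - m) * var
            ).astype(x.dtype)
        else:
            mean = self.params["running_mean"]
            var = self.params["running_var"]
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(bs)) * inv.reshape(bs)
        y = self.params["gamma"].reshape(bs) * xhat + self.params["beta"].reshape(bs)
        self._cache = (xhat, inv, axes, bs, training)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, axes, bs, training = self._cache
        self.grads["gamma"] += (dy * xhat).sum(axis=axes)
        self.grads["beta"] += dy.sum(axis=axes)
        g = self.params["gamma"].reshape(bs)
        if not training:
            return dy * g * inv.reshape(bs)
        m = float(np.prod([dy.shape[a] for a in axes]))
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes).reshape(bs)
            - xhat * (dxhat * xhat).mean(axis=axes).reshape(bs)
        ) * inv.reshape(bs)
        return dx


class MaxPool(Layer):
    """Non-overlapping max pooling with window == stride; trailing voxels
    that do not fill a window are dropped (floor semantics)."""

    def __init__(self, ndim: int, kernel: int) -> None:
        super().__init__()
        self.ndim = ndim
        self.kernel = kernel

    def out_spatial(self, spatial: tuple[int, ...]) -> tuple[int, ...]:
        out = tuple(s // self.kernel for s in spatial)
        if any(s < 1 for s in out):
            raise ValueError(
                f"{self.name or 'maxpool'}: extent {spatial} smaller than "
                f"pool window {self.kernel}"
            )
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        k = self.kernel
        spatial = x.shape[2:]
        out_sp = self.out_spatial(spatial)
        crop = (slice(None), slice(None)) + tuple(slice(0, o * k) for o in out_sp)
        xc = x[crop]
        n, c = x.shape[:2]
        # interleave (out, k) per axis, then bring the k axes last
        shape = (n, c) + tuple(v for o in out_sp for v in (o, k))
        xr = xc.reshape(shape)
        order = [0, 1] + [2 + 2 * i for i in range(self.ndim)] + [
            3 + 2 * i for i in range(self.ndim)
        ]
        xr = xr.transpose(order).reshape((n, c) + out_sp + (k**self.ndim,))
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, spatial, out_sp, idx)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, spatial, out_sp, idx = self._cache
        k = self.kernel
        n, c = x_shape[:2]
        dxr = np.zeros((n, c) + out_sp + (k**self.ndim,), dtype=dy.dtype)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
        # invert the transpose/reshape of forward
        dxr = dxr.reshape((n, c) + out_sp + (k,) * self.ndim)
        order = [0, 1]
        for i in range(self.ndim):
            order += [2 + i, 2 + self.ndim + i]
        dxc = dxr.transpose(order).reshape(
            (n, c) + tuple(o * k for o in out_sp)
        )
        dx = np.zeros(x_shape, dtype=dy.dtype)
        crop = (slice(None), slice(None)) + tuple(slice(0, o * k) for o in out_sp)
        dx[crop] = dxc
        return dx


class GlobalAveragePool(Layer):
    """Reduce each feature map to its spatial mean: (N, C, *S) -> (N, C)."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._cache = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        shape = self._cache
        z = float(np.prod(shape[2:]))
        dx = np.broadcast_to(
            dy.reshape(dy.shape + (1,) * (len(shape) - 2)), shape
        )
        return (dx / z).astype(dy.dtype)


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._cache = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._cache)


class Dense(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        relu: bool = False,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        init: str = "uniform",
        dtype=np.float32,
    ) -> None:
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.relu = relu
        self.use_bias = bias
        rng = rng or np.random.default_rng(0)
        if init == "uniform":
            w = rng.uniform(-1.0, 1.0, size=(in_features, out_features))
        elif init == "he":
            w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features))
        else:
            raise ValueError(f"unknown init {init!r}")
        self.params["w"] = w.astype(dtype)
        if bias:
            self.params["b"] = np.zeros(out_features, dtype=dtype)
        self.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        y = x @ self.params["w"]
        if self.use_bias:
            y = y + self.params["b"]
        if self.relu:
            y = np.maximum(y, 0.0)
        self._cache = (x, y if self.relu else None)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, post = self._cache
        if self.relu:
            dy = np.where(post > 0, dy, 0.0)
        self.grads["w"] += x.T @ dy
        if self.use_bias:
            self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["w"].T


class Dropout(Layer):
    """Inverted dropout; identity outside training mode.

    The mask stream comes from the generator handed in at construction so a
    whole training run is reproducible from one seed.
    """

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._cache = None
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        self._cache = mask
        return x * mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cache is None:
            return dy
        return dy * self._cache


class Sequential:
    """Ordered layer chain with cached forward and partial backward."""

    def __init__(self, layers: Sequence[Layer]) -> None:
        self.layers = list(layers)
        for i, layer in enumerate(self.layers):
            if not layer.name:
                layer.name = f"{type(layer).__name__.lower()}_{i}"

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    __call__ = forward

    def forward_cached(self, x: np.ndarray, training: bool = False) -> list[np.ndarray]:
        """Forward pass returning every layer's output (index-aligned)."""
        outputs = []
        for layer in self.layers:
            x = layer.forward(x, training=training)
            outputs.append(x)
        return outputs

    def backward(self, dy: np.ndarray, stop_at: int = 0,
                 need_input_grad: bool = True) -> np.ndarray:
        """Propagate an output-side gradient back to (and including) layer
        ``stop_at``; the return value is the gradient with respect to the
        *output* of layer ``stop_at - 1`` (the network input for 0).

        With ``need_input_grad=False`` the gradient with respect to the
        innermost layer's input is skipped — a worthwhile saving when the
        chain starts with an expensive convolution and only parameter
        gradients are wanted (i.e. training).
        """
        for i in range(len(self.layers) - 1, stop_at - 1, -1):
            layer = self.layers[i]
            if i == stop_at and not need_input_grad and isinstance(layer, Conv):
                return layer.backward(dy, need_input_grad=False)
            dy = layer.backward(dy)
        return dy

    def grad_at_layer(self, index: int, dy: np.ndarray) -> np.ndarray:
        """Gradient of a scalar (seeded by ``dy`` at the network output)
        with respect to the output of layer ``index``.  Requires a prior
        ``forward_cached`` call."""
        return self.backward(dy, stop_at=index + 1)

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def trainable_params(self):
        for layer in self.layers:
            for key in layer.trainable():
                yield layer, key

    def state(self) -> dict[str, np.ndarray]:
        return {
            f"{layer.name}.{key}": value.copy()
            for layer in self.layers
            for key, value in layer.params.items()
        }

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for layer in self.layers:
            for key in layer.params:
                layer.params[key] = np.array(state[f"{layer.name}.{key}"])


class Adam:
    """Adam with bias-corrected moments (eps 1e-8 by default)."""

    def __init__(
        self,
        net: Sequential,
        learning_rate: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.net = net
        self.lr = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m: dict[tuple[int, str], np.ndarray] = {}
        self.v: dict[tuple[int, str], np.ndarray] = {}
        for i, layer in enumerate(net.layers):
            for key in layer.trainable():
                self.m[(i, key)] = np.zeros_like(layer.params[key])
                self.v[(i, key)] = np.zeros_like(layer.params[key])

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for i, layer in enumerate(self.net.layers):
            for key in layer.trainable():
                g = layer.grads[key]
                m = self.m[(i, key)]
                v = self.v[(i, key)]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                update = (m / corr1) / (np.sqrt(v / corr2) + self.eps)
                layer.params[key] -= (self.lr * update).astype(layer.params[key].dtype)
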