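"""Training loop for the nodule classifiers, statsmodels-style.

The study protocol is: feed volumes through the network, apply softmax to
the two class scores, optimize the mean cross-entropy with Adam (learning
rate 1e-4, beta1 0.9, beta2 0.999), and monitor a held-out validation set
every epoch; the untouched test set is consulted once at the very end.

The public surface mirrors statsmodels: :class:`NoduleClassifier` is built
from data plus an architecture description, its :meth:`fit` returns a
:class:`ClassifierResults` carrying the trained parameters, the per-epoch
history, a ``summary()`` table, prediction and evaluation methods, and a
``grad_cam`` hook.  Thin functional wrappers (:func:`train`,
:func:`predict`, :func:`cross_entropy_loss`) expose the same machinery for
scripting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .architectures import (
    ModelHandle,
    NetworkDescription,
    build_model,
    canonical_description,
)
from .evaluation import MetricsReport, evaluate_predictions
from .gradcam import Heatmap, grad_cam
from .phantom import PhantomSample, SplitManifest

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "NoduleClassifier",
    "ClassifierResults",
    "cross_entropy_loss",
    "softmax",
    "train",
    "predict",
]


def softmax(scores: np.ndarray) -> np.ndarray:
    """Row-wise softmax in a shift-stable form."""
    scores = np.asarray(scores, dtype=np.float64)
    shifted = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_loss(
    scores: np.ndarray, labels: np.ndarray, return_grad: bool = False
):
    """Mean negative log softmax probability of the true class.

    ``scores`` are pre-softmax, one row per sample, two columns.  Computed
    via log-sum-exp so extreme scores neither overflow nor underflow.  With
    ``return_grad`` the analytic gradient (softmax minus one-hot, divided
    by the batch size) is returned alongside.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.ndim != 2:
        raise ValueError("scores must be 2-dimensional (samples, classes)")
    if np.any((labels != 0) & (labels != 1)):
        raise ValueError("labels must be 0 or 1")
    n = scores.shape[0]
    shifted = scores - scores.max(axis=1, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=1))
    log_p_true = shifted[np.arange(n), labels] - lse
    loss = float(-log_p_true.mean())
    if not return_grad:
        return loss
    grad = softmax(scores)
    grad[np.arange(n), labels] -= 1.0
    grad /= n
    return loss, grad


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol; the Adam hyperparameters are the study's."""

    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    early_stop_patience: int | None = 10

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        for name in ("beta1", "beta2"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch log; ``best_epoch`` indexes the minimum validation loss
    (earliest on ties)."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    @property
    def best_epoch(self) -> int:
        if not self.val_loss:
            raise ValueError("no epochs recorded")
        return int(np.argmin(self.val_loss))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(self.n_epochs),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "val_accuracy": self.val_accuracy,
            }
        )


def _forward_batched(net, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
    """Inference forward pass in chunks.

    The convolution layers materialize work buffers proportional to the
    batch size (the first layer's unrolled matrix in particular), so large
    evaluation sets are pushed through in slices to keep peak memory flat.
    """
    outs = [
        net.forward(x[start : start + batch_size], training=False)
        for start in range(0, x.shape[0], batch_size)
    ]
    return np.concatenate(outs, axis=0)


def _stack_volumes(volumes, dtype=np.float32) -> np.ndarray:
    arr = np.asarray(
        [s.volume if isinstance(s, PhantomSample) else s for s in volumes],
        dtype=dtype,
    )
    if arr.ndim == 4:  # (n, d, h, w) single channel
        arr = arr[:, None]
    return arr


class NoduleClassifier:
    """Binary nodule classifier bound to training (and validation) data.

    Parameters
    ----------
    endog : array-like
        Binary labels of the training volumes (1 = nodule).
    exog : array-like
        Training volumes, shape (n, edge, edge, edge) or (n, 1, ...).
    validation : tuple (volumes, labels), optional
        Held-out set monitored every epoch.
    description : NetworkDescription | str
        Architecture to fit; a name selects the canonical description
        (default: the lightweight proposed 3D CNN).
    standardize : str | bool
        ``"scale"`` (default) divides by the training-set standard
        deviation only, keeping the background at the zero level shared by
        convolution padding; ``"zscore"`` additionally subtracts the mean
        (classical standardization); ``False`` disables the transform.
        The fitted transform is applied to all later inputs as well.
    """

    def __init__(
        self,
        endog,
        exog,
        validation: tuple | None = None,
        description: NetworkDescription | str = "proposed3d",
        standardize: str | bool = "scale",
        init: str = "uniform",
        dtype=np.float32,
    ) -> None:
        if isinstance(description, str):
            description = canonical_description(description)
        self.description = description
        self.labels = np.asarray(endog, dtype=np.int64)
        self.volumes = _stack_volumes(exog, dtype)
        if self.volumes.shape[1:] != tuple(description.input_shape):
            raise ValueError(
                f"volume shape {self.volumes.shape[1:]} does not match the "
                f"model input {tuple(description.input_shape)}"
            )
        if self.labels.shape[0] != self.volumes.shape[0]:
            raise ValueError("labels and volumes disagree in length")
        if validation is not None:
            vx, vy = validation
            self.val_volumes = _stack_volumes(vx, dtype)
            self.val_labels = np.asarray(vy, dtype=np.int64)
        else:
            self.val_volumes = self.val_labels = None
        if standardize is True:
            standardize = "zscore"
        self.standardize = standardize
        self.init = init
        self.dtype = dtype
        if standardize == "zscore":
            self.loc = float(self.volumes.mean())
            self.scale = float(self.volumes.std()) or 1.0
        elif standardize == "scale":
            self.loc = 0.0
            self.scale = float(self.volumes.std()) or 1.0
        elif standardize is False:
            self.loc, self.scale = 0.0, 1.0
        else:
            raise ValueError(f"unknown standardize mode {standardize!r}")

    @classmethod
    def from_samples(
        cls,
        samples: list[PhantomSample],
        manifest: SplitManifest,
        **kwargs,
    ) -> "NoduleClassifier":
        """Build from a phantom collection and its split manifest, using
        the train split as data and the validation split as monitor."""
        labels = np.array([s.label for s in samples])
        tr = manifest.indices("train")
        va = manifest.indices("validation")
        val = (
            ([samples[i] for i in va], labels[va]) if va.size else None
        )
        return cls(labels[tr], [samples[i] for i in tr], validation=val, **kwargs)

    def _transform(self, volumes: np.ndarray) -> np.ndarray:
        return ((volumes - self.loc) / self.scale).astype(self.dtype)

    def fit(self, config: TrainConfig | None = None,
            verbose: bool = False) -> "ClassifierResults":
        """Run the Adam training loop and return the results object.

        The model with the lowest validation loss is retained (training
        continues from the final state, but the results carry the best
        parameters); with ``early_stop_patience`` set, training stops after
        that many epochs without a new validation-loss minimum.
        """
        config = config or TrainConfig()
        if self.val_volumes is None:
            raise ValueError("fit requires a non-empty validation set")
        model = build_model(
            self.description, seed=config.seed, dtype=self.dtype, init=self.init
        )
        x = self._transform(self.volumes)
        xv = self._transform(self.val_volumes)
        opt = nn.Adam(model.net, config.learning_rate, config.beta1,
                      config.beta2, config.epsilon)
        rng = np.random.default_rng(config.seed)
        history = TrainHistory()
        best_state = model.net.state()
        best_val = np.inf
        since_best = 0
        n = x.shape[0]
        for epoch in range(config.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                scores = model.net.forward(x[idx], training=True)
                loss, grad = cross_entropy_loss(
                    scores, self.labels[idx], return_grad=True
                )
                model.net.zero_grad()
                model.net.backward(grad.astype(self.dtype), need_input_grad=False)
                opt.step()
                epoch_loss += loss * idx.size
            val_scores = _forward_batched(model.net, xv, config.batch_size)
            val_loss = cross_entropy_loss(val_scores, self.val_labels)
            val_acc = float(
                (val_scores.argmax(axis=1) == self.val_labels).mean()
            )
            history.train_loss.append(epoch_loss / n)
            history.val_loss.append(val_loss)
            history.val_accuracy.append(val_acc)
            if verbose:
                print(
                    f"epoch {epoch:3d}  train_loss {epoch_loss / n:.4f}  "
                    f"val_loss {val_loss:.4f}  val_acc {val_acc:.3f}"
                )
            if val_loss < best_val:
                best_val = val_loss
                best_state = model.net.state()
                since_best = 0
            else:
                since_best += 1
                if (
                    config.early_stop_patience is not None
                    and since_best >= config.early_stop_patience
                ):
                    break
        model.net.load_state(best_state)
        return ClassifierResults(self, model, config, history)


class ClassifierResults:
    """Fitted classifier: trained parameters, history and diagnostics."""

    def __init__(
        self,
        model: NoduleClassifier,
        handle: ModelHandle,
        config: TrainConfig,
        history: TrainHistory,
    ) -> None:
        self.model = model
        self.handle = handle
        self.config = config
        self.history = history
        self._test_evaluations: dict[int, int] = {}

    def predict(self, volumes) -> np.ndarray:
        """Class-1 (nodule) softmax probability per volume, order preserved."""
        return self.predict_proba(volumes)[:, 1]

    def predict_proba(self, volumes) -> np.ndarray:
        """Both class probabilities, shape (n, 2)."""
        x = self.model._transform(_stack_volumes(volumes, self.model.dtype))
        return softmax(_forward_batched(self.handle.net, x))

    def validate(self) -> MetricsReport:
        """Metrics on the validation set; repeatable at will."""
        probs = self.predict(self.model.val_volumes)
        return evaluate_predictions(self.model.val_labels, probs)

    def evaluate(self, volumes, labels, threshold: float = 0.5) -> MetricsReport:
        probs = self.predict(volumes)
        return evaluate_predictions(np.asarray(labels), probs, threshold)

    def evaluate_test(self, volumes, labels, manifest: SplitManifest | None = None,
                      threshold: float = 0.5) -> MetricsReport:
        """Metrics on the held-out test set.

        The study design allows exactly one look at the test set; a second
        call against the same manifest emits a warning so the breach is
        visible in logs and warning filters.
        """
        key = id(manifest)
        self._test_evaluations[key] = self._test_evaluations.get(key, 0) + 1
        if self._test_evaluations[key] > 1:
            warnings.warn(
                "test set evaluated more than once for this manifest; the "
                "study design reserves it for a single final evaluation",
                UserWarning,
                stacklevel=2,
            )
        return self.evaluate(volumes, labels, threshold)

    def grad_cam(self, volume, class_index: int = 1,
                 target_layer: str | int | None = None) -> Heatmap:
        """Saliency heatmap for one (standardized) input volume."""
        vol = np.asarray(volume.volume if isinstance(volume, PhantomSample)
                         else volume)
        if vol.ndim == len(self.handle.input_shape) - 1:
            vol = vol[None]
        x = self.model._transform(vol.astype(self.model.dtype))
        return grad_cam(self.handle, x, class_index, target_layer)

    def summary(self) -> str:
        h = self.history
        desc = self.handle.description
        lines = [
            "Nodule classifier fit",
            "=" * 54,
            f"architecture:        {desc.name}",
            f"input shape:         {tuple(desc.input_shape)}",
            f"total parameters:    {desc.total_parameters()}",
            f"optimizer:           Adam(lr={self.config.learning_rate}, "
            f"b1={self.config.beta1}, b2={self.config.beta2})",
            f"epochs run:          {h.n_epochs} (of {self.config.epochs})",
            f"best epoch:          {h.best_epoch}",
            f"train loss (final):  {h.train_loss[-1]:.4f}",
            f"val loss (best):     {h.val_loss[h.best_epoch]:.4f}",
            f"val accuracy (best): {h.val_accuracy[h.best_epoch]:.4f}",
            "=" * 54,
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        """Checkpoint: parameters + normalization + config, as ``.npz``."""
        state = self.handle.net.state()
        meta = {
            "arch": self.handle.description.name,
            "seed": self.handle.seed,
            "init": self.handle.init,
            "loc": self.model.loc,
            "scale": self.model.scale,
            **{f"cfg_{k}": v for k, v in asdict(self.config).items()
               if v is not None},
        }
        np.savez(path, __meta__=np.array([repr(meta)]), **state)


def train(
    model: ModelHandle | None,
    samples: list[PhantomSample],
    manifest: SplitManifest,
    config: TrainConfig | None = None,
    **kwargs,
):
    """Functional wrapper: fit on the manifest's train/validation splits.

    Returns ``(results, history)``; ``model`` may be None to build the
    default lightweight 3D CNN, or a :class:`ModelHandle` whose
    description is reused.
    """
    description = model.description if model is not None else "proposed3d"
    clf = NoduleClassifier.from_samples(
        samples, manifest, description=description, **kwargs
    )
    results = clf.fit(config)
    return results, results.history


def predict(results: ClassifierResults, volumes) -> np.ndarray:
    """Class-1 probability per volume (functional alias)."""
    return results.predict(volumes)
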