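"""Synthetic 3D nodule phantoms with voxel-level ground truth.

The classifier's study design needs balanced sets of small cubic CT crops,
half containing a nodule and half containing only distractor anatomy.  In
place of patient data, this module synthesizes such crops: a flat
background, a handful of bright vessel-like cylinders crossing the volume,
optionally one bright quasi-ellipsoidal nodule at a random interior
position, and additive Gaussian noise.  Every positive sample carries the
exact binary mask of its nodule, which later serves as the ground truth
for checking that class-activation maps point at the right voxels.

Intensities are abstract floats (no Hounsfield calibration); training code
standardizes them to zero mean and unit variance.  With the noise turned
off the task is separable by a plain intensity threshold — the generator
therefore comes with a tiny threshold classifier that tests use to confirm
the task is well-posed before any network is trained.

All sampling is driven by ``numpy.random.default_rng`` seeded per sample
from a root seed, so datasets are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "PhantomConfig",
    "PhantomSample",
    "SplitManifest",
    "generate_sample",
    "generate_dataset",
    "make_splits",
    "threshold_classifier_accuracy",
    "easy_config",
]

SPLIT_NAMES = ("train", "validation", "test")


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and intensity of one phantom family.

    Defaults target the 27-voxel cubic input of the lightweight 3D CNN;
    use ``edge=32`` for the AlexNet variants.  ``nodule_intensity`` is the
    peak contrast of the nodule over the background; vessels are dimmer
    (``vessel_intensity``) so that maximum brightness separates the
    classes when noise is off.
    """

    edge: int = 27
    nodule_radius_range: tuple[float, float] = (3.0, 6.0)
    nodule_intensity: float = 1.0
    vessel_count_range: tuple[int, int] = (1, 4)
    vessel_radius_range: tuple[float, float] = (1.0, 2.0)
    vessel_intensity: float = 0.5
    noise_sd: float = 0.1
    background_level: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.nodule_radius_range
        if not 0 < lo <= hi:
            raise ValueError("nodule radius range must be positive and ordered")
        if hi >= self.edge / 2:
            raise ValueError(
                f"max nodule radius {hi} must be < edge/2 = {self.edge / 2}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.vessel_count_range[0] < 0:
            raise ValueError("vessel count must be >= 0")


def easy_config(edge: int = 27) -> PhantomConfig:
    """The noiseless, high-contrast configuration: intensity-separable by
    construction, used for end-to-end training checks."""
    return PhantomConfig(edge=edge, noise_sd=0.0, nodule_intensity=1.0,
                         vessel_intensity=0.5)


@dataclass
class PhantomSample:
    """One labeled volume: ``label`` 1 means a nodule is present and
    ``mask`` marks exactly its voxels (empty for label 0)."""

    volume: np.ndarray
    label: int
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)


def _coordinate_grid(edge: int) -> np.ndarray:
    ax = np.arange(edge, dtype=np.float64)
    return np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1)


def _add_vessels(volume: np.ndarray, config: PhantomConfig,
                 rng: np.random.Generator) -> None:
    edge = config.edge
    n = int(rng.integers(config.vessel_count_range[0],
                         config.vessel_count_range[1] + 1))
    if n == 0:
        return
    grid = _coordinate_grid(edge)
    for _ in range(n):
        point = rng.uniform(0, edge, size=3)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = rng.uniform(*config.vessel_radius_range)
        rel = grid - point
        along = rel @ direction
        dist2 = (rel * rel).sum(axis=-1) - along**2
        inside = dist2 <= radius**2
        # vessels are homogeneous tissue: overlaps do not stack, so the
        # brightest non-nodule voxel never exceeds vessel_intensity
        volume[inside] = np.maximum(
            volume[inside], config.background_level + config.vessel_intensity
        )


def _add_nodule(volume: np.ndarray, config: PhantomConfig,
                rng: np.random.Generator) -> np.ndarray:
    edge = config.edge
    radius = rng.uniform(*config.nodule_radius_range)
    # quasi-ellipsoid: independent per-axis squash/stretch of +-20%
    semi = radius * rng.uniform(0.8, 1.2, size=3)
    margin = float(np.ceil(semi.max())) + 1.0
    if 2 * margin >= edge:
        raise ValueError("nodule radius range infeasible for this edge length")
    center = rng.uniform(margin, edge - margin, size=3)
    grid = _coordinate_grid(edge)
    d2 = (((grid - center) / semi) ** 2).sum(axis=-1)
    mask = d2 <= 1.0
    # smooth radial profile, strictly positive on every mask voxel
    profile = np.where(mask, 1.0 - 0.5 * d2, 0.0)
    volume += config.nodule_intensity * profile
    return mask


def generate_sample(config: PhantomConfig, label: int, seed: int) -> PhantomSample:
    """One phantom volume; identical (config, label, seed) are bit-identical."""
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    rng = np.random.default_rng(seed)
    edge = config.edge
    volume = np.full((edge,) * 3, config.background_level, dtype=np.float64)
    _add_vessels(volume, config, rng)
    if label == 1:
        mask = _add_nodule(volume, config, rng)
    else:
        mask = np.zeros((edge,) * 3, dtype=bool)
    if config.noise_sd > 0:
        volume += rng.normal(0.0, config.noise_sd, size=volume.shape)
    return PhantomSample(
        volume=volume.astype(np.float32),
        label=label,
        mask=mask,
        provenance={"seed": int(seed), "label": int(label), **asdict(config)},
    )


def generate_dataset(
    config: PhantomConfig,
    n_positive: int,
    n_negative: int,
    seed: int,
) -> list[PhantomSample]:
    """A shuffled balanced-or-not collection with per-sample derived seeds.

    Sample seeds are spawned from the root seed, and the final order is a
    seed-determined permutation, so the whole collection is reproducible.
    """
    if n_positive < 1 or n_negative < 1:
        raise ValueError("need at least one sample per class")
    rng = np.random.default_rng(seed)
    labels = np.array([1] * n_positive + [0] * n_negative)
    sample_seeds = rng.integers(0, 2**31 - 1, size=labels.size)
    order = rng.permutation(labels.size)
    return [
        generate_sample(config, int(labels[i]), int(sample_seeds[i]))
        for i in order
    ]


@dataclass
class SplitManifest:
    """Per-sample assignment to train/validation/test, stratified by label."""

    assignments: list[str]
    seed: int

    def __post_init__(self) -> None:
        bad = set(self.assignments) - set(SPLIT_NAMES)
        if bad:
            raise ValueError(f"unknown split names: {sorted(bad)}")

    def indices(self, split: str) -> np.ndarray:
        if split not in SPLIT_NAMES:
            raise ValueError(f"unknown split {split!r}")
        return np.array([i for i, s in enumerate(self.assignments) if s == split])

    @property
    def counts(self) -> dict[str, int]:
        return {s: self.assignments.count(s) for s in SPLIT_NAMES}


def make_splits(
    labels,
    train_fraction: float = 0.7,
    validation_fraction: float = 0.1,
    seed: int = 0,
) -> SplitManifest:
    """Stratified three-way split following the study design.

    ``train_fraction`` of the data goes to training and the rest to test;
    ``validation_fraction`` *of the training set* is then carved out for
    validation (and removed from the effective training set).  With 2,000
    balanced samples at the default fractions this yields 1,400 - 140 =
    1,260 effective training, 140 validation and 600 test volumes.
    Stratification keeps each split's class balance within one sample of
    the global ratio.
    """
    labels = np.asarray(labels)
    n = labels.size
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    if not 0 <= validation_fraction < 1:
        raise ValueError("validation_fraction must lie in [0, 1)")
    n_train = int(round(train_fraction * n))
    n_val = int(round(validation_fraction * n_train))
    if n_train - n_val < 1 or n - n_train < 1:
        raise ValueError("split fractions leave an empty train or test set")
    classes = np.unique(labels)
    class_sizes = np.array([np.sum(labels == c) for c in classes])
    train_quota = _largest_remainder(train_fraction * class_sizes, n_train)
    val_quota = _largest_remainder(validation_fraction * train_quota, n_val)
    rng = np.random.default_rng(seed)
    assignments = np.empty(n, dtype=object)
    for cls, n_tr, n_va in zip(classes, train_quota, val_quota):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        assignments[idx[:n_va]] = "validation"
        assignments[idx[n_va:n_tr]] = "train"
        assignments[idx[n_tr:]] = "test"
    return SplitManifest(assignments=list(assignments), seed=seed)


def _largest_remainder(shares: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation summing exactly to ``total``, proportional to
    ``shares`` (largest fractional parts win the leftover units)."""
    base = np.floor(shares).astype(int)
    base = np.minimum(base, np.ceil(shares).astype(int))
    leftover = total - int(base.sum())
    if leftover > 0:
        order = np.argsort(-(shares - base), kind="stable")
        for i in order[:leftover]:
            base[i] += 1
    return base


def threshold_classifier_accuracy(samples: list[PhantomSample]) -> float:
    """Best achievable accuracy of a max-intensity threshold rule.

    This is the generator's separability oracle: on noiseless
    high-contrast phantoms it reaches 1.0, and it degrades as ``noise_sd``
    grows — establishing that a trained network's performance target is
    attainable before any training runs.
    """
    scores = np.array([float(s.volume.max()) for s in samples])
    labels = np.array([s.label for s in samples])
    order = np.argsort(scores)
    scores_sorted = scores[order]
    labels_sorted = labels[order]
    n = labels.size
    best = max(labels.mean(), 1 - labels.mean())
    # threshold between consecutive distinct scores
    npos_right = np.cumsum(labels_sorted[::-1])[::-1]
    nneg_left = np.cumsum(1 - labels_sorted) - (1 - labels_sorted)
    for i in range(n):
        if i > 0 and scores_sorted[i] == scores_sorted[i - 1]:
            continue
        acc = (npos_right[i] + nneg_left[i]) / n
        best = max(best, float(acc))
    return best
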