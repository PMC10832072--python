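"""Two-stage curriculum training and the imbalance baselines.

The estimators in :mod:`mosaicsoft.estimators` do the heavy lifting; this
module provides the procedural surface around them — inverse-frequency class
weights, oversampling with replacement, the soft-label cross-entropy, and
``train_stage1`` / ``train_stage2`` / ``predict`` operating on lists of
:class:`~mosaicsoft.synthetic.LabeledImage`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from mosaicsoft.augment import AugmentationPolicy
from mosaicsoft.estimators import SoftLabelCNNClassifier, _one_hot
from mosaicsoft.mosaic import MosaicImage
from mosaicsoft.synthetic import LabeledImage, images_to_arrays

__all__ = [
    "TrainConfig",
    "class_weights",
    "oversample",
    "oversample_arrays",
    "soft_label_loss",
    "train_stage1",
    "train_stage2",
    "predict",
]


@dataclass
class TrainConfig:
    """Training hyperparameters shared by all recipes.

    ``backbone`` names the classifier architecture ('small_cnn' is the only
    built-in); ``pretrained`` keeps the transfer-learning protocol of a
    frozen-feature head-training phase before full fine-tuning;
    ``fine_tune_learning_rate`` must be below ``learning_rate`` since
    fine-tuning retrains the whole network at a low rate.
    """

    backbone: str = "small_cnn"
    pretrained: bool = True
    channels: tuple[int, ...] = (16, 32, 64, 64)
    epochs: int = 20
    head_epochs: int = 2
    batch_size: int = 32
    learning_rate: float = 1e-2
    fine_tune_learning_rate: float = 3e-3
    validation_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fine_tune_learning_rate >= self.learning_rate:
            raise ValueError("fine_tune_learning_rate must be < learning_rate")
        if self.backbone != "small_cnn":
            raise ValueError(f"unknown backbone {self.backbone!r}")

    def make_estimator(self, **overrides) -> SoftLabelCNNClassifier:
        params = dict(
            channels=self.channels,
            epochs=self.epochs,
            head_epochs=self.head_epochs if self.pretrained else 0,
            learning_rate=self.learning_rate,
            fine_tune_learning_rate=self.fine_tune_learning_rate,
            batch_size=self.batch_size,
            validation_fraction=self.validation_fraction,
            random_state=self.seed,
        )
        params.update(overrides)
        return SoftLabelCNNClassifier(**params)


def class_weights(counts) -> np.ndarray:
    """Inverse-frequency loss weights ``w_c = total / (K * n_c)``.

    Misclassifications of a minority class are penalized more heavily; the
    product ``w_c * n_c`` is the same for every class, so each class
    contributes equally to the expected loss.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts <= 0):
        raise ValueError("all class counts must be positive")
    return counts.sum() / (len(counts) * counts)


def oversample(images: list[LabeledImage], seed: int = 0) -> list[LabeledImage]:
    """Resample minority classes with replacement up to the majority count.

    Already-balanced input is returned unchanged; appended samples are drawn
    with replacement from their own class.  Deterministic given ``seed``.
    """
    labels = np.array([im.label for im in images])
    classes, counts = np.unique(labels, return_counts=True)
    if len(images) == 0:
        raise ValueError("cannot oversample an empty dataset")
    majority = counts.max()
    if np.all(counts == majority):
        return list(images)
    rng = np.random.default_rng(seed)
    out = list(images)
    for c, n_c in zip(classes, counts):
        deficit = int(majority - n_c)
        if deficit == 0:
            continue
        members = [im for im in images if im.label == c]
        out.extend(members[int(i)] for i in rng.integers(len(members), size=deficit))
    return out


def oversample_arrays(
    X: np.ndarray, y: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Array variant of :func:`oversample` for (n, H, W, 3) image stacks."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    majority = counts.max()
    if np.all(counts == majority):
        return X, y
    rng = np.random.default_rng(seed)
    extra = []
    for c, n_c in zip(classes, counts):
        deficit = int(majority - n_c)
        if deficit:
            members = np.flatnonzero(y == c)
            extra.append(members[rng.integers(len(members), size=deficit)])
    idx = np.concatenate([np.arange(len(y)), *extra])
    return X[idx], y[idx]


def soft_label_loss(
    result: np.ndarray, label: np.ndarray, eps: float = 1e-12
) -> float:
    """Cross-entropy ``-sum_c label[c] * log(result[c])`` in nats.

    ``result`` must be a probability vector; one-hot labels are the special
    case that recovers ordinary cross-entropy.  Zero predicted probabilities
    where the label is positive are clamped at ``eps`` (with a warning) so
    the loss stays finite.
    """
    result = np.asarray(result, dtype=float)
    label = np.asarray(label, dtype=float)
    if np.any((result <= 0) & (label > 0)):
        warnings.warn(
            "zero predicted probability at a positive-label class; clamping",
            stacklevel=2,
        )
    return float(-np.sum(label * np.log(np.clip(result, eps, None))))


def _require_all_classes(images: list[LabeledImage], n_classes: int) -> None:
    present = {im.label for im in images}
    missing = set(range(n_classes)) - present
    if missing:
        raise ValueError(f"classes {sorted(missing)} absent from the training split")


def train_stage1(
    train: list[LabeledImage],
    val: list[LabeledImage] | None,
    config: TrainConfig,
    n_classes: int = 3,
) -> SoftLabelCNNClassifier:
    """Stage 1: conventional class-weighted training on the original images.

    Head training at the base learning rate is followed by full-network
    fine-tuning at the lower rate; the best-validation checkpoint is kept.
    """
    _require_all_classes(train, n_classes)
    X, y = images_to_arrays(train)
    est = config.make_estimator(class_weight="balanced")
    if val:
        Xv, yv = images_to_arrays(val)
        return est.fit(X, y, X_val=Xv, y_val=yv)
    return est.fit(X, y)


def train_stage2(
    stage1_model: SoftLabelCNNClassifier,
    train: list[LabeledImage],
    mosaic_dataset: list[MosaicImage],
    val: list[LabeledImage] | None,
    config: TrainConfig,
    stage2_init: str = "pretrained_base",
    class_weight: bool = False,
    n_classes: int = 3,
) -> SoftLabelCNNClassifier:
    """Stage 2: retrain on original one-hot plus mosaic soft-label samples.

    Weights restart from the base initialization by default
    (``stage2_init='stage1_weights'`` continues from stage 1 instead).
    Original images keep the full augmentation policy; mosaics get flips and
    small rotations only.  An empty mosaic dataset falls back to stage-1
    training with a warning.
    """
    if not mosaic_dataset:
        warnings.warn("empty mosaic dataset: falling back to stage-1 training",
                      stacklevel=2)
        return train_stage1(train, val, config, n_classes)
    _require_all_classes(train, n_classes)
    X, y = images_to_arrays(train)
    Xm = np.stack([m.pixels for m in mosaic_dataset])
    Ym = np.stack([m.soft_label.probs for m in mosaic_dataset]).astype(np.float32)
    X2 = np.concatenate([X, Xm])
    Y2 = np.concatenate([_one_hot(y, n_classes), Ym])
    policies = [AugmentationPolicy.stage1()] * len(X) + [
        AugmentationPolicy.mosaic()
    ] * len(Xm)
    sample_weight = None
    if class_weight:
        cw = class_weights(np.bincount(y, minlength=n_classes))
        sample_weight = np.concatenate([cw[y], np.ones(len(Xm))]).astype(np.float32)
    est = config.make_estimator(class_weight=None)
    init_state = (
        stage1_model.backbone_.state_dict()
        if stage2_init == "stage1_weights"
        else None
    )
    kwargs = dict(
        sample_weight=sample_weight, sample_policy=policies, init_state=init_state
    )
    if val:
        Xv, yv = images_to_arrays(val)
        return est.fit(X2, Y2, X_val=Xv, y_val=yv, **kwargs)
    return est.fit(X2, Y2, **kwargs)


def predict(model, images: list[LabeledImage]) -> list[tuple[np.ndarray, int]]:
    """Per-image result vectors and argmax classes (lowest index on ties).

    Prediction consumes real images only; mosaics exist solely for training.
    """
    X, _ = images_to_arrays(images)
    probs = model.predict_proba(X)
    return [(p, int(np.argmax(p))) for p in probs]
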