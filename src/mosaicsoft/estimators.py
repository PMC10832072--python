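"""Scikit-learn style classifiers wrapping the numpy CNN backbone.

Two estimators cover the training recipes:

:class:`SoftLabelCNNClassifier`
    A small CNN image classifier trained with (optionally class-weighted)
    cross-entropy on hard or soft labels, per-sample augmentation policies,
    a head-then-full fine-tuning schedule, and best-validation checkpointing.
    With ``class_weight='balanced'`` this is the weight-balancing (WB)
    recipe; trained on resampled data it is the oversampling (OS) recipe.

:class:`MosaicCurriculumClassifier`
    The two-stage curriculum: stage 1 fits the weight-balanced model on the
    original images, builds a mosaic soft-label dataset from it, then stage 2
    re-initializes and trains on original + mosaic images together.

Both follow the scikit-learn estimator contract (``get_params`` /
``set_params``, fitted attributes with trailing underscores) and compose
with ``sklearn.base.clone`` and model selection utilities.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from mosaicsoft.augment import AugmentationPolicy, augment_image
from mosaicsoft.mosaic import MosaicConfig, build_mosaic_dataset
from mosaicsoft.nn import Adam, SmallCNN
from mosaicsoft.synthetic import LabeledImage

__all__ = [
    "SoftLabelCNNClassifier",
    "MosaicCurriculumClassifier",
    "save_model",
    "load_model",
]


def _as_float01(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim != 4 or X.shape[-1] != 3:
        raise ValueError(f"X must be (n, H, W, 3), got {X.shape}")
    if X.shape[1] != X.shape[2]:
        raise ValueError("images must be square")
    if X.dtype == np.uint8:
        return X.astype(np.float32) / 255.0
    X = X.astype(np.float32)
    if X.size and X.max() > 1.5:  # 0-255 floats
        X = X / 255.0
    return X


def _one_hot(y: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((len(y), k), dtype=np.float32)
    out[np.arange(len(y)), y] = 1.0
    return out


class SoftLabelCNNClassifier(ClassifierMixin, BaseEstimator):
    """Small-CNN image classifier accepting hard or soft labels.

    Parameters
    ----------
    channels:
        Conv channel widths of the backbone; pooling after all but the last.
    epochs:
        Full-network fine-tuning epochs at ``fine_tune_learning_rate``.
    head_epochs:
        Initial epochs training only the dense head at ``learning_rate``
        (the transfer-learning warm-up of the protocol).
    learning_rate, fine_tune_learning_rate:
        Adam step sizes; the fine-tuning rate must be the smaller one.
    batch_size:
        Minibatch size.
    class_weight:
        None, ``'balanced'`` (weights ``n / (K * n_c)``), or an array of
        per-class weights, applied to hard-labeled samples.
    augmentation:
        Default :class:`AugmentationPolicy` applied to every training image
        (None disables augmentation); per-sample policies can be passed to
        :meth:`fit`.
    validation_fraction:
        Fraction of the training data held out (stratified) for checkpoint
        selection when no explicit validation set is given; 0 disables
        checkpointing (final weights are kept).
    init_seed:
        Seed of the backbone's base weight initialization.  Fixed by default
        so independent fits share the same 'pretrained base' starting point.
    random_state:
        Seed of shuffling, augmentation draws and the validation split.
    """

    def __init__(
        self,
        channels: tuple[int, ...] = (16, 32, 64, 64),
        epochs: int = 20,
        head_epochs: int = 2,
        learning_rate: float = 1e-2,
        fine_tune_learning_rate: float = 3e-3,
        batch_size: int = 32,
        class_weight=None,
        augmentation: AugmentationPolicy | None = AugmentationPolicy.stage1(),
        validation_fraction: float = 0.15,
        init_seed: int = 0,
        random_state: int | None = 0,
    ) -> None:
        self.channels = channels
        self.epochs = epochs
        self.head_epochs = head_epochs
        self.learning_rate = learning_rate
        self.fine_tune_learning_rate = fine_tune_learning_rate
        self.batch_size = batch_size
        self.class_weight = class_weight
        self.augmentation = augmentation
        self.validation_fraction = validation_fraction
        self.init_seed = init_seed
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _resolve_targets(self, y) -> tuple[np.ndarray, np.ndarray]:
        y = np.asarray(y)
        if y.ndim == 1:
            classes = np.unique(y)
            k = len(classes)
            lookup = {c: i for i, c in enumerate(classes)}
            encoded = np.array([lookup[v] for v in y])
            return classes, _one_hot(encoded, k)
        if y.ndim == 2:
            if np.any(y < -1e-9) or np.any(np.abs(y.sum(axis=1) - 1) > 1e-6):
                raise ValueError("soft-label rows must be probability vectors")
            return np.arange(y.shape[1]), y.astype(np.float32)
        raise ValueError("y must be 1-D hard labels or a 2-D soft-label matrix")

    def _class_weights(self, targets: np.ndarray) -> np.ndarray | None:
        if self.class_weight is None:
            return None
        k = targets.shape[1]
        if isinstance(self.class_weight, str):
            if self.class_weight != "balanced":
                raise ValueError(f"unknown class_weight {self.class_weight!r}")
            counts = targets.sum(axis=0)
            if np.any(counts <= 0):
                raise ValueError("class_weight='balanced' needs every class present")
            return (targets.sum() / (k * counts)).astype(np.float32)
        w = np.asarray(self.class_weight, dtype=np.float32)
        if w.shape != (k,) or np.any(w <= 0):
            raise ValueError("class_weight array must hold K positive weights")
        return w

    def fit(
        self,
        X,
        y,
        X_val=None,
        y_val=None,
        sample_weight: np.ndarray | None = None,
        sample_policy: list[AugmentationPolicy | None] | None = None,
        init_state: dict | None = None,
    ):
        """Fit the classifier.

        ``y`` may be integer labels or an (n, K) soft-label matrix.
        ``sample_policy`` optionally overrides the augmentation policy per
        sample (None entries disable augmentation for that sample);
        ``init_state`` starts training from a given backbone state dict
        instead of the base initialization.
        """
        if self.fine_tune_learning_rate >= self.learning_rate:
            raise ValueError(
                "fine_tune_learning_rate must be below learning_rate "
                "(fine-tuning retrains the whole network at a low rate)"
            )
        X = _as_float01(X)
        self.classes_, targets = self._resolve_targets(y)
        n, size = len(X), X.shape[1]
        if len(targets) != n:
            raise ValueError("X and y length mismatch")
        k = targets.shape[1]

        cw = self._class_weights(targets)
        if sample_weight is not None:
            weights = np.asarray(sample_weight, dtype=np.float32).copy()
        else:
            weights = np.ones(n, dtype=np.float32)
        if cw is not None:
            hard = np.isclose(targets.max(axis=1), 1.0)
            weights[hard] *= cw[targets[hard].argmax(axis=1)]

        policies: list[AugmentationPolicy | None]
        if sample_policy is not None:
            if len(sample_policy) != n:
                raise ValueError("sample_policy length mismatch")
            policies = list(sample_policy)
        else:
            policies = [self.augmentation] * n

        rng = np.random.default_rng(self.random_state)
        if X_val is not None:
            Xv = _as_float01(X_val)
            yv = np.searchsorted(self.classes_, np.asarray(y_val))
        elif self.validation_fraction and n >= 10:
            strat = targets.argmax(axis=1)
            idx_tr, idx_val = train_test_split(
                np.arange(n),
                test_size=self.validation_fraction,
                random_state=int(rng.integers(2**31 - 1)),
                stratify=strat if np.min(np.bincount(strat)) >= 2 else None,
            )
            Xv, yv = X[idx_val], strat[idx_val]
            X, targets, weights = X[idx_tr], targets[idx_tr], weights[idx_tr]
            policies = [policies[i] for i in idx_tr]
            n = len(X)
        else:
            Xv = yv = None

        self.n_fit_samples_ = n
        self.backbone_ = SmallCNN(
            image_size=size, n_classes=k, channels=self.channels, seed=self.init_seed
        )
        if init_state is not None:
            self.backbone_.load_state_dict(init_state)

        self.history_ = []
        self._best_state = None
        self.best_val_score_ = -np.inf
        for phase, n_epochs, lr, head_only in (
            ("head", self.head_epochs, self.learning_rate, True),
            ("fine_tune", self.epochs, self.fine_tune_learning_rate, False),
        ):
            if n_epochs <= 0:
                continue
            opt = Adam(self.backbone_.parameters(head_only=head_only), lr=lr)
            for epoch in range(n_epochs):
                order = rng.permutation(n)
                losses, lweights = [], []
                for start in range(0, n, self.batch_size):
                    idx = order[start : start + self.batch_size]
                    batch = np.empty((len(idx), size, size, 3), dtype=np.float32)
                    for j, i in enumerate(idx):
                        pol = policies[i]
                        batch[j] = (
                            X[i] if pol is None else augment_image(X[i], pol, rng)
                        )
                    loss, grads = self.backbone_.loss_and_grads(
                        batch, targets[idx], weights[idx], head_only=head_only
                    )
                    opt.step(grads)
                    losses.append(loss * weights[idx].sum())
                    lweights.append(weights[idx].sum())
                record = {
                    "phase": phase,
                    "epoch": epoch,
                    "train_loss": float(np.sum(losses) / np.sum(lweights)),
                }
                if Xv is not None:
                    val_acc = float(
                        np.mean(self.backbone_.predict_proba(Xv).argmax(axis=1) == yv)
                    )
                    record["val_accuracy"] = val_acc
                    if val_acc >= self.best_val_score_:
                        self.best_val_score_ = val_acc
                        self._best_state = self.backbone_.state_dict()
                self.history_.append(record)

        if self._best_state is not None:
            self.backbone_.load_state_dict(self._best_state)
        elif Xv is None:
            self.best_val_score_ = float("nan")
        self.n_features_in_ = size * size * 3
        return self

    # ------------------------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "backbone_")
        return self.backbone_.predict_proba(_as_float01(X))

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)

    def predict(self, X) -> np.ndarray:
        # argmax takes the lowest index on ties
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def cam_data(self, image01: np.ndarray, target_class: int):
        """Grad-CAM hook: designated-layer activations and logit gradients."""
        check_is_fitted(self, "backbone_")
        return self.backbone_.cam_data(image01, target_class)


class MosaicCurriculumClassifier(ClassifierMixin, BaseEstimator):
    """Two-stage curriculum with mosaic-based soft labeling (MBS).

    Stage 1 trains a class-weighted model on the original images.  Its
    Grad-CAM representative regions seed a mosaic soft-label dataset of
    ``n_mosaics`` images; stage 2 then trains on the concatenation of the
    original one-hot samples (full augmentation) and the mosaic soft-label
    samples (flips and small rotations only).

    Parameters
    ----------
    estimator:
        Template :class:`SoftLabelCNNClassifier` cloned for each stage;
        a default one is used when None.  Stage 1 always uses
        ``class_weight='balanced'``; stage 2 applies class weights only when
        ``stage2_class_weight`` is set (the mosaic dataset already carries an
        oversampling effect, so they are off by default).
    n_mosaics:
        Number of synthesized mosaic images (1,200 in the reference setup).
    oversample_allocation:
        Per-class probability of holding the dominant quadrant; uniform when
        None.
    stage2_init:
        ``'pretrained_base'`` restarts stage 2 from the base initialization;
        ``'stage1_weights'`` continues from the stage-1 weights.
    random_state:
        Seed for the mosaic builder (the stage estimators carry their own).
    """

    def __init__(
        self,
        estimator: SoftLabelCNNClassifier | None = None,
        n_mosaics: int = 1200,
        oversample_allocation: tuple[float, ...] | None = None,
        stage2_init: str = "pretrained_base",
        stage2_class_weight: bool = False,
        random_state: int | None = 0,
    ) -> None:
        self.estimator = estimator
        self.n_mosaics = n_mosaics
        self.oversample_allocation = oversample_allocation
        self.stage2_init = stage2_init
        self.stage2_class_weight = stage2_class_weight
        self.random_state = random_state

    def _template(self) -> SoftLabelCNNClassifier:
        return (
            SoftLabelCNNClassifier()
            if self.estimator is None
            else clone(self.estimator)
        )

    def fit(self, X, y, X_val=None, y_val=None):
        """Run both curriculum stages on hard-labeled images ``(X, y)``."""
        if self.stage2_init not in ("pretrained_base", "stage1_weights"):
            raise ValueError("stage2_init must be 'pretrained_base' or 'stage1_weights'")
        X = np.asarray(X)
        y = np.asarray(y)
        if X.dtype != np.uint8:
            raise ValueError("MosaicCurriculumClassifier expects uint8 images")

        stage1 = self._template()
        stage1.set_params(class_weight="balanced")
        stage1.fit(X, y, X_val=X_val, y_val=y_val)
        self.stage1_ = stage1
        self.classes_ = stage1.classes_
        k = len(self.classes_)

        lookup = {c: i for i, c in enumerate(self.classes_)}
        images = [
            LabeledImage(pixels=X[i], label=lookup[y[i]], id=f"train_{i:05d}")
            for i in range(len(X))
        ]
        seed = 0 if self.random_state is None else int(self.random_state)
        config = MosaicConfig(
            n_images=self.n_mosaics,
            oversample_allocation=self.oversample_allocation,
            output_size=X.shape[1],
            seed=seed,
        )
        self.mosaics_ = build_mosaic_dataset(images, stage1, config, n_classes=k)

        if not self.mosaics_:
            warnings.warn(
                "empty mosaic dataset: falling back to stage-1 training",
                stacklevel=2,
            )
            self.stage2_ = stage1
            return self

        Xm = np.stack([m.pixels for m in self.mosaics_])
        Ym = np.stack([m.soft_label.probs for m in self.mosaics_]).astype(np.float32)
        encoded = np.array([lookup[v] for v in y])
        X2 = np.concatenate([X, Xm])
        Y2 = np.concatenate([_one_hot(encoded, k), Ym])

        stage2 = self._template()
        stage2.set_params(class_weight=None)
        real_policy = stage2.augmentation or AugmentationPolicy.stage1()
        policies = [real_policy] * len(X) + [AugmentationPolicy.mosaic()] * len(Xm)

        sample_weight = None
        if self.stage2_class_weight:
            counts = np.bincount(encoded, minlength=k)
            cw = len(X) / (k * counts)
            sample_weight = np.concatenate(
                [cw[encoded], np.ones(len(Xm))]
            ).astype(np.float32)

        init_state = (
            self.stage1_.backbone_.state_dict()
            if self.stage2_init == "stage1_weights"
            else None
        )
        stage2.fit(
            X2,
            Y2,
            X_val=X_val,
            y_val=y_val,
            sample_weight=sample_weight,
            sample_policy=policies,
            init_state=init_state,
        )
        self.stage2_ = stage2
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "stage2_")
        return self.stage2_.predict_proba(X)

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "stage2_")
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def cam_data(self, image01: np.ndarray, target_class: int):
        check_is_fitted(self, "stage2_")
        return self.stage2_.cam_data(image01, target_class)


def save_model(model, path) -> None:
    """Save a fitted classifier's backbone and metadata as an ``.npz`` file.

    A :class:`MosaicCurriculumClassifier` is saved through its stage-2
    model (the deployable artifact of the curriculum).
    """
    if isinstance(model, MosaicCurriculumClassifier):
        check_is_fitted(model, "stage2_")
        model = model.stage2_
    check_is_fitted(model, "backbone_")
    bb = model.backbone_
    arrays = {
        "image_size": np.array(bb.image_size),
        "n_classes": np.array(bb.n_classes),
        "channels": np.array(bb.channels),
        "classes": np.asarray(model.classes_),
        "dense_W": bb.dense_W,
        "dense_b": bb.dense_b,
    }
    for i, (w, b) in enumerate(zip(bb.conv_W, bb.conv_b)):
        arrays[f"conv_W_{i}"] = w
        arrays[f"conv_b_{i}"] = b
    np.savez(path, **arrays)


def load_model(path) -> SoftLabelCNNClassifier:
    """Load a classifier saved by :func:`save_model`, ready for prediction."""
    with np.load(path) as data:
        channels = tuple(int(c) for c in data["channels"])
        est = SoftLabelCNNClassifier(channels=channels)
        est.backbone_ = SmallCNN(
            image_size=int(data["image_size"]),
            n_classes=int(data["n_classes"]),
            channels=channels,
        )
        est.backbone_.load_state_dict(
            {
                "conv_W": [data[f"conv_W_{i}"] for i in range(len(channels))],
                "conv_b": [data[f"conv_b_{i}"] for i in range(len(channels))],
                "dense_W": data["dense_W"],
                "dense_b": data["dense_b"],
            }
        )
        est.classes_ = data["classes"]
        est.n_features_in_ = int(data["image_size"]) ** 2 * 3
    return est
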