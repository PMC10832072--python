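"""Scaled-down end-to-end comparison of the three imbalance remedies.

Runs the full study protocol on the synthetic lesion dataset: generate an
imbalanced dataset, split it (stratified test set first, then train/val),
train the weight-balancing (WB), oversampling (OS) and mosaic-based soft
labeling (MBS) models, and score all three on the common test set.  The WB
model doubles as stage 1 of the curriculum, exactly as in the protocol,
where the first model is the one "trained only up to stage 1".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mosaicsoft.curriculum import (
    TrainConfig,
    oversample,
    train_stage1,
    train_stage2,
)
from mosaicsoft.metrics import MetricsReport, evaluate_predictions
from mosaicsoft.mosaic import (
    MosaicConfig,
    build_mosaic_dataset,
    inverse_frequency_allocation,
)
from mosaicsoft.synthetic import (
    SyntheticDatasetConfig,
    generate_dataset,
    images_to_arrays,
    split_dataset,
)

__all__ = ["ComparisonConfig", "run_comparison"]

CLASS_NAMES = ["cancer-like", "opmd-like", "noncancer-like"]


@dataclass
class ComparisonConfig:
    """Problem sizes of the scaled-down comparison.

    Defaults reproduce the study conditions at desk scale: ~500 images at
    the 372:141:1297 ratio, 32-px images, a tiny CNN, a mosaic dataset
    scaled to the train-split size, and the dominant quadrant allocated
    inversely to class frequency (the by-area oversampling of minorities).
    """

    n_total: int = 500
    image_size: int = 32
    imbalance_ratio: tuple[float, ...] = (372.0, 141.0, 1297.0)
    n_mosaics: int = 240
    allocation: str | tuple[float, ...] | None = "inverse_frequency"
    epochs: int = 20
    channels: tuple[int, ...] = (16, 32, 64, 64)
    seed: int = 0


def run_comparison(
    config: ComparisonConfig | None = None, **overrides
) -> dict[str, MetricsReport]:
    """Train WB, OS and MBS on one synthetic dataset; score on its test set.

    Returns ``{"WB": report, "OS": report, "MBS": report}``; feed the dict
    to :func:`mosaicsoft.metrics.comparison_report` for the side-by-side
    table.  Deterministic given ``config.seed``.
    """
    if config is None:
        config = ComparisonConfig(**overrides)
    data_cfg = SyntheticDatasetConfig(
        n_total=config.n_total,
        image_size=config.image_size,
        imbalance_ratio=config.imbalance_ratio,
        seed=config.seed,
    )
    images = generate_dataset(data_cfg)
    train, val, test = split_dataset(images, seed=config.seed)
    n_classes = len(config.imbalance_ratio)
    train_cfg = TrainConfig(
        epochs=config.epochs, channels=config.channels, seed=config.seed
    )

    # WB: stage 1 of the curriculum, evaluated as a model in its own right
    wb = train_stage1(train, val, train_cfg, n_classes)

    # OS: same recipe on a resampled (class-balanced) training split
    os_train = oversample(train, seed=config.seed)
    Xos, yos = images_to_arrays(os_train)
    Xv, yv = images_to_arrays(val)
    os_model = train_cfg.make_estimator(class_weight=None).fit(
        Xos, yos, X_val=Xv, y_val=yv
    )

    # MBS: mosaic soft-label dataset from the stage-1 model, then stage 2
    counts = np.bincount([im.label for im in train], minlength=n_classes)
    if config.allocation == "inverse_frequency":
        allocation = inverse_frequency_allocation(counts)
    else:
        allocation = config.allocation
    mosaic_cfg = MosaicConfig(
        n_images=config.n_mosaics,
        oversample_allocation=allocation,
        output_size=config.image_size,
        seed=config.seed,
    )
    mosaics = build_mosaic_dataset(train, wb, mosaic_cfg, n_classes)
    mbs = train_stage2(wb, train, mosaics, val, train_cfg, n_classes=n_classes)

    Xt, yt = images_to_arrays(test)
    return {
        name: evaluate_predictions(
            yt, model.predict(Xt), n_classes, class_names=CLASS_NAMES
        )
        for name, model in (("WB", wb), ("OS", os_model), ("MBS", mbs))
    }
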