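import numpy as np
import pytest

from mosaicsoft.estimators import SoftLabelCNNClassifier
from mosaicsoft.synthetic import (
    SyntheticDatasetConfig,
    generate_dataset,
    images_to_arrays,
)


@pytest.fixture(scope="session")
def balanced_images():
    """Small balanced 3-class dataset (32 px) shared across tests."""
    cfg = SyntheticDatasetConfig(
        n_per_class=20, imbalance_ratio=(1, 1, 1), image_size=32, seed=11
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def imbalanced_images():
    """Small imbalanced dataset at the default 372:141:1297 ratio."""
    cfg = SyntheticDatasetConfig(n_total=120, image_size=32, seed=3)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def trained_model(balanced_images):
    """A quickly trained classifier used by the Grad-CAM pipeline tests."""
    X, y = images_to_arrays(balanced_images)
    est = SoftLabelCNNClassifier(
        epochs=6,
        head_epochs=1,
        augmentation=None,
        validation_fraction=0.0,
        random_state=7,
    )
    return est.fit(X, y)
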