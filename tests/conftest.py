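import numpy as np
import pytest

import fedleaf as fl


@pytest.fixture(scope="session")
def small_dataset() -> fl.LabeledImageSet:
    """4 classes x 30 images, 32x32, mild noise — the workhorse fixture."""
    spec = fl.SyntheticDatasetSpec(
        n_classes=4, images_per_class=30, image_size=(32, 32),
        noise_level=0.1, seed=7,
    )
    return fl.make_dataset(spec)


@pytest.fixture(scope="session")
def clean_dataset() -> fl.LabeledImageSet:
    """Noise-free 4 classes x 50 for separability oracles."""
    spec = fl.SyntheticDatasetSpec(
        n_classes=4, images_per_class=50, image_size=(32, 32),
        noise_level=0.0, seed=1,
    )
    return fl.make_dataset(spec)


@pytest.fixture
def tiny_model_spec() -> fl.ModelSpec:
    return fl.ModelSpec(
        architecture="tiny_cnn", n_classes=4, input_size=(32, 32), init_seed=3
    )


def nearest_centroid_predict(
    train_images: np.ndarray,
    train_labels: np.ndarray,
    query: np.ndarray,
    n_classes: int,
) -> np.ndarray:
    """Brute-force nearest-mean-template classifier (oracle)."""
    templates = np.stack(
        [train_images[train_labels == c].mean(axis=0) for c in range(n_classes)]
    )
    d = ((query[:, None] - templates[None]) ** 2).sum(axis=(2, 3, 4))
    return d.argmin(axis=1)
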