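"""Synthetic PlantVillage-style leaf-image datasets.

Renders deterministic, class-separable "leaf" images: each class has a
distinct base hue and a class-specific lesion motif (number, size, darkness
and placement of spots drawn from a per-class parameter table), with one
lesion-free healthy class per dataset.  The goal is not photorealism but the
statistical structure the federated pipeline depends on: multi-class,
balanced, visually discriminative patterns, and a difficulty dial
(``noise_level``).

Datasets round-trip to disk in the class-per-directory layout used by the
public PlantVillage archives: ``<root>/<class_name>/<image_id>.png``.
"""

from __future__ import annotations

import colorsys
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

_IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg"}

#: Class rosters of the four PlantVillage datasets used downstream
#: (grape, apple and corn with 4 classes, tomato with 10; one healthy class
#: each).  ``images_per_class`` defaults stay desk-scale; pass
#: ``images_per_class`` explicitly to scale up.
DATASET_PRESETS: dict[str, list[str]] = {
    "grape": ["Black_rot", "Black_Measles", "Leaf_blight", "Healthy"],
    "apple": ["Apple_scab", "Black_rot", "Cedar_apple_rust", "Healthy"],
    "corn": ["Leaf_spot", "Common_rust", "Healthy", "Leaf_blight"],
    "tomato": [
        "Bacterial_spot",
        "Early_blight",
        "Late_blight",
        "Leaf_mold",
        "Septoria_leaf_spot",
        "Two_spotted_spider_mite",
        "Target_spot",
        "Yellow_leaf_curl_virus",
        "Mosaic_virus",
        "Healthy",
    ],
}


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Parameters of one synthetic dataset.

    Attributes
    ----------
    name:
        Dataset label; if it matches a preset ("grape", "apple", "corn",
        "tomato") the preset class roster is used and ``n_classes`` must
        agree with it.
    n_classes:
        Number of leaf classes (>= 2), one of which is healthy.
    images_per_class:
        Images rendered per class (>= 1); labels are exactly balanced.
    image_size:
        (height, width) in pixels, both >= 8.
    noise_level:
        Amplitude in [0, 1] of i.i.d. Gaussian pixel noise; 0 keeps classes
        separable by a nearest-class-template rule.
    seed:
        Seed of the single RNG that drives all rendering randomness;
        identical specs produce bit-identical datasets.
    """

    name: str = "synthetic"
    n_classes: int = 4
    images_per_class: int = 30
    image_size: tuple[int, int] = (32, 32)
    noise_level: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.images_per_class < 1:
            raise ValueError(
                f"images_per_class must be >= 1, got {self.images_per_class}"
            )
        h, w = self.image_size
        if h < 8 or w < 8:
            raise ValueError(
                f"image_size dimensions must be >= 8, got {self.image_size}"
            )
        if not 0.0 <= self.noise_level <= 1.0:
            raise ValueError(
                f"noise_level must lie in [0, 1], got {self.noise_level}"
            )
        preset = DATASET_PRESETS.get(self.name)
        if preset is not None and self.n_classes != len(preset):
            raise ValueError(
                f"preset dataset {self.name!r} has {len(preset)} classes, "
                f"spec says n_classes={self.n_classes}"
            )

    def class_names(self) -> list[str]:
        preset = DATASET_PRESETS.get(self.name)
        if preset is not None:
            return list(preset)
        names = [f"disease_{c}" for c in range(1, self.n_classes)]
        return ["Healthy"] + names


@dataclass
class LabeledImageSet:
    """In-memory image dataset: float images in [0, 1] plus integer labels."""

    images: np.ndarray  # (n, height, width, 3) float64 in [0, 1]
    labels: np.ndarray  # (n,) int
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim != 4 or self.images.shape[-1] != 3:
            raise ValueError(
                f"images must have shape (n, h, w, 3), got {self.images.shape}"
            )
        if len(self.images) != len(self.labels):
            raise ValueError(
                f"{len(self.images)} images but {len(self.labels)} labels"
            )
        k = len(self.class_names)
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= k):
            raise ValueError("labels must index class_names")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, indices) -> "LabeledImageSet":
        idx = np.asarray(indices, dtype=np.int64)
        return LabeledImageSet(
            self.images[idx], self.labels[idx], list(self.class_names)
        )


# ---------------------------------------------------------------------------
# rendering


def _class_palette(c: int, n_classes: int) -> tuple[np.ndarray, dict]:
    """Base leaf color and lesion parameters for class index ``c``.

    Hues are spread evenly around the wheel so class templates are far apart
    in RGB space; the lesion table varies spot count, radius, darkness and
    placement spread per class.
    """
    hue = (c + 0.37) / n_classes
    base = np.array(colorsys.hsv_to_rgb(hue, 0.55, 0.75))
    lesion = {
        "n_spots": 2 + 2 * (c % 4),
        "radius_frac": 0.06 + 0.03 * (c % 3),
        "darkness": 0.45 + 0.1 * (c % 2),
        "spread": 0.25 + 0.08 * (c % 3),  # stddev of spot centers, leaf frac
    }
    return base, lesion


def _render_image(
    rng: np.random.Generator,
    c: int,
    n_classes: int,
    healthy: bool,
    shape: tuple[int, int],
    noise_level: float,
) -> np.ndarray:
    h, w = shape
    base, lesion = _class_palette(c, n_classes)

    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    # elliptical leaf silhouette on a dark soil background
    r2 = ((yy - cy) / (0.48 * h)) ** 2 + ((xx - cx) / (0.40 * w)) ** 2
    leaf_mask = r2 <= 1.0

    img = np.empty((h, w, 3))
    img[:] = np.array([0.12, 0.10, 0.08])  # background
    shading = 1.0 - 0.25 * r2  # mild radial shading inside the leaf
    for ch in range(3):
        img[..., ch] = np.where(leaf_mask, base[ch] * shading, img[..., ch])

    if not healthy:
        spot_color = base * (1.0 - lesion["darkness"]) + np.array(
            [0.35, 0.18, 0.05]
        ) * lesion["darkness"]
        n_spots = int(rng.integers(lesion["n_spots"], lesion["n_spots"] + 3))
        for _ in range(n_spots):
            sy = cy + rng.normal(0.0, lesion["spread"]) * h
            sx = cx + rng.normal(0.0, lesion["spread"]) * w
            radius = max(1.0, lesion["radius_frac"] * min(h, w) * rng.uniform(0.7, 1.4))
            d2 = (yy - sy) ** 2 + (xx - sx) ** 2
            spot = (d2 <= radius**2) & leaf_mask
            blend = np.exp(-d2 / (2.0 * radius**2))
            for ch in range(3):
                img[..., ch] = np.where(
                    spot,
                    img[..., ch] * (1 - blend) + spot_color[ch] * blend,
                    img[..., ch],
                )

    if noise_level > 0:
        img = img + rng.normal(0.0, noise_level, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def make_dataset(spec: SyntheticDatasetSpec) -> LabeledImageSet:
    """Render the dataset described by ``spec``.

    Returns exactly ``n_classes * images_per_class`` images with balanced
    labels, ordered class-by-class.  A single RNG seeded by ``spec.seed``
    drives every random draw, so identical specs yield bit-identical pixels.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    class_names = spec.class_names()
    h, w = spec.image_size

    images = np.empty((spec.n_classes * spec.images_per_class, h, w, 3))
    labels = np.empty(len(images), dtype=np.int64)
    i = 0
    for c, name in enumerate(class_names):
        healthy = name.lower() == "healthy"
        for _ in range(spec.images_per_class):
            images[i] = _render_image(
                rng, c, spec.n_classes, healthy, (h, w), spec.noise_level
            )
            labels[i] = c
            i += 1
    return LabeledImageSet(images, labels, class_names)


# ---------------------------------------------------------------------------
# splitting


def stratified_split(
    data: LabeledImageSet, test_fraction: float, seed: int
) -> tuple[LabeledImageSet, LabeledImageSet]:
    """Seeded train/test split with per-class proportions within one image.

    Test counts are allocated by cumulative rounding across classes, so the
    total test size tracks ``test_fraction`` exactly even when per-class
    counts do not divide evenly (e.g. two classes of 5 at 0.5 split 3/2 and
    2/3).  Train and test are disjoint and jointly cover ``data``.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    cum = 0.0
    taken = 0
    for c in range(data.n_classes):
        cls = np.flatnonzero(data.labels == c)
        if len(cls) < 2:
            raise ValueError(
                f"class {data.class_names[c]!r} has {len(cls)} examples; "
                "need >= 2 to split"
            )
        cum += len(cls) * test_fraction
        n_test = int(np.floor(cum + 0.5)) - taken
        n_test = min(max(n_test, 1), len(cls) - 1)  # keep both sides non-empty
        taken += n_test
        perm = rng.permutation(len(cls))
        test_idx.append(cls[perm[:n_test]])
        train_idx.append(cls[perm[n_test:]])
    train = np.sort(np.concatenate(train_idx))
    test = np.sort(np.concatenate(test_idx))
    return data.subset(train), data.subset(test)


# ---------------------------------------------------------------------------
# disk round trip


def write_dataset(data: LabeledImageSet, root) -> None:
    """Write ``data`` as 8-bit PNGs in class-per-directory layout."""
    root = Path(root)
    if root.exists() and any(root.iterdir()):
        raise FileExistsError(f"refusing to write into non-empty directory {root}")
    for c, name in enumerate(data.class_names):
        cls_dir = root / name
        cls_dir.mkdir(parents=True, exist_ok=True)
        for j, i in enumerate(np.flatnonzero(data.labels == c)):
            arr = np.round(data.images[i] * 255.0).astype(np.uint8)
            Image.fromarray(arr).save(cls_dir / f"{name}_{j:05d}.png")


def read_dataset(root) -> LabeledImageSet:
    """Read a class-per-directory image dataset.

    Class names are the subdirectory names in lexicographic order.  Files
    without an image extension are skipped with a warning; an empty class
    directory is an error.  Pixels come back as floats in [0, 1], within
    8-bit quantization of what was written.
    """
    root = Path(root)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise FileNotFoundError(f"no class subdirectories under {root}")
    images, labels = [], []
    class_names = [d.name for d in class_dirs]
    for c, d in enumerate(class_dirs):
        files = sorted(f for f in d.iterdir() if f.is_file())
        kept = 0
        for f in files:
            if f.suffix.lower() not in _IMAGE_EXTENSIONS:
                warnings.warn(f"skipping non-image file {f}", stacklevel=2)
                logger.warning("skipping non-image file %s", f)
                continue
            with Image.open(f) as im:
                arr = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
            images.append(arr)
            labels.append(c)
            kept += 1
        if kept == 0:
            raise ValueError(f"class directory {d} contains no images")
    shapes = {im.shape for im in images}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent image shapes on disk: {shapes}")
    return LabeledImageSet(np.stack(images), np.asarray(labels), class_names)
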