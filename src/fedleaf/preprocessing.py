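"""Image preprocessing: bilinear resize and per-channel standardization.

The two transformations the pipeline applies before federation: resize all
images to one (height, width), and standardize each channel as
``Z = (X - m) / sigma`` using the empirical per-channel mean ``m`` and
population standard deviation ``sigma``.  Stats are meant to be computed on
the training split only and applied unchanged to test data, so both splits
see the same distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .synthetic_data import LabeledImageSet


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel mean ``m`` and standard deviation ``sigma`` (> 0)."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=np.float64))
        object.__setattr__(self, "std", np.asarray(self.std, dtype=np.float64))
        if self.mean.shape != self.std.shape:
            raise ValueError("mean and std must have the same shape")
        if np.any(self.std <= 0):
            raise ValueError("std must be strictly positive in every channel")

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelStats":
        return cls(np.asarray(d["mean"]), np.asarray(d["std"]))


def resize_images(
    data: LabeledImageSet, target: tuple[int, int]
) -> LabeledImageSet:
    """Bilinearly resize every image to ``target`` = (height, width).

    Labels are untouched.  When the target equals the current size the
    images are returned as an exact copy (no interpolation error).
    """
    th, tw = int(target[0]), int(target[1])
    if th < 1 or tw < 1:
        raise ValueError(f"target dimensions must be >= 1, got {target}")
    h, w = data.images.shape[1:3]
    if (th, tw) == (h, w):
        return LabeledImageSet(
            data.images.copy(), data.labels.copy(), list(data.class_names)
        )
    out = np.empty((len(data), th, tw, 3))
    for i in range(len(data)):
        out[i] = _sk_resize(
            data.images[i],
            (th, tw),
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
    return LabeledImageSet(out, data.labels.copy(), list(data.class_names))


def compute_channel_stats(data: LabeledImageSet) -> ChannelStats:
    """Per-channel mean and population std over all pixels of all images."""
    if len(data) == 0:
        raise ValueError("cannot compute channel stats of an empty dataset")
    pixels = data.images.reshape(-1, data.images.shape[-1])
    mean = pixels.mean(axis=0)
    std = pixels.std(axis=0)  # population (ddof=0)
    # constant channels can come out ~1e-17 instead of exactly 0
    degenerate = std < 1e-12
    if np.any(degenerate):
        bad = [int(c) for c in np.flatnonzero(degenerate)]
        raise ValueError(
            f"zero-variance channel(s) {bad}: sigma must be > 0 to normalize"
        )
    return ChannelStats(mean, std)


def normalize(data: LabeledImageSet, stats: ChannelStats) -> LabeledImageSet:
    """Standardize each channel: ``Z = (X - m) / sigma``."""
    n_channels = data.images.shape[-1]
    if stats.mean.shape != (n_channels,):
        raise ValueError(
            f"stats have {stats.mean.shape[0]} channels, images have {n_channels}"
        )
    z = (data.images - stats.mean) / stats.std
    return LabeledImageSet(z, data.labels.copy(), list(data.class_names))


def denormalize(data: LabeledImageSet, stats: ChannelStats) -> LabeledImageSet:
    """Invert :func:`normalize`: ``X = Z * sigma + m``."""
    x = data.images * stats.std + stats.mean
    return LabeledImageSet(x, data.labels.copy(), list(data.class_names))
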