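"""Synthetic labeled texture datasets and the noisy-query protocol.

The generator emulates a multi-class grayscale texture database: each class
is a parameterized texture family with distinct spatial statistics —
oriented sinusoidal gratings (class-specific frequency and orientation),
checkerboards (class-specific period), and smoothed-noise blob fields
(class-specific correlation length) — with per-image random phase, offset
and orientation jitter so images within a class vary but remain
recognizable.  Intensities live on the 0-255 scale.

The noise protocol mirrors a clean-database / degraded-query benchmark:
zero-mean additive white Gaussian noise with a per-image standard deviation
drawn uniformly from ``[sigma_min, sigma_max]`` (default 5 to 50 on the
0-255 scale) is added to each image, and the noisy copies serve as queries
against the clean database.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class SyntheticDataset:
    """Images, per-image class labels and unique ids, plus generator params."""

    images: List[np.ndarray]
    labels: List[str]
    ids: List[str]
    spec: Dict

    def __post_init__(self) -> None:
        if not (len(self.images) == len(self.labels) == len(self.ids)):
            raise ValueError("images, labels and ids must have equal length")
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("image ids must be unique")

    def label_map(self) -> Dict[str, str]:
        return dict(zip(self.ids, self.labels))


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian noise band on the 0-255 intensity scale."""

    sigma_min: float = 5.0
    sigma_max: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.sigma_min <= self.sigma_max:
            raise ValueError(
                f"need 0 < sigma_min <= sigma_max, got "
                f"({self.sigma_min}, {self.sigma_max})"
            )


@dataclass(frozen=True)
class NoisyQueryProtocol:
    """Clean database plus one noisy query per database image."""

    database: SyntheticDataset
    queries: SyntheticDataset
    pairs: Dict[str, str]  # query id -> clean database id


def _grating(size: int, freq: float, angle: float, phase: float,
             amp: float) -> np.ndarray:
    y, x = np.mgrid[0:size, 0:size].astype(np.float64)
    u = x * np.cos(angle) + y * np.sin(angle)
    return 127.5 + amp * np.sin(2.0 * np.pi * freq * u / size + phase)


def _checkerboard(size: int, period: int, oy: float, ox: float) -> np.ndarray:
    y, x = np.mgrid[0:size, 0:size].astype(np.float64)
    cells = np.floor((y + oy) / period) + np.floor((x + ox) / period)
    return np.where(cells % 2 == 0, 40.0, 215.0)


def _blobs(size: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal((size, size))
    smooth = ndimage.gaussian_filter(noise, sigma, mode="wrap")
    lo, hi = smooth.min(), smooth.max()
    return 255.0 * (smooth - lo) / (hi - lo) if hi > lo else np.full_like(smooth, 127.5)


def _render_class_image(family: int, level: int, size: int,
                        rng: np.random.Generator) -> np.ndarray:
    if family == 0:  # oriented grating; frequency and orientation grow with level
        freq = 4.0 + 5.0 * level
        angle = np.deg2rad(30.0 * level + rng.uniform(-8.0, 8.0))
        phase = rng.uniform(0.0, 2.0 * np.pi)
        amp = rng.uniform(90.0, 110.0)
        img = _grating(size, freq, angle, phase, amp)
    elif family == 1:  # checkerboard; period shrinks with level
        period = max(3, size // (6 + 4 * level))
        img = _checkerboard(size, period, rng.uniform(0, period), rng.uniform(0, period))
    else:  # blob field; correlation length shrinks with level
        sigma = max(1.0, 6.0 / (1 + level))
        img = _blobs(size, sigma, rng)
    return np.clip(img, 0.0, 255.0)


def generate_texture_dataset(
    n_classes: int = 4,
    n_per_class: int = 25,
    size: int = 64,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a labeled multi-class texture dataset, deterministic under seed.

    Classes cycle through three texture families (grating, checkerboard,
    blobs) with family parameters stepped every cycle, so any number of
    classes >= 2 yields statistically distinct textures.
    """
    if n_classes < 2:
        raise ValueError(f"need at least 2 classes, got {n_classes}")
    if n_per_class < 1:
        raise ValueError(f"need at least 1 image per class, got {n_per_class}")
    if size < 32:
        raise ValueError(f"image size must be >= 32, got {size}")
    rng = np.random.default_rng(seed)
    images, labels, ids = [], [], []
    for c in range(n_classes):
        family, level = c % 3, c // 3
        for k in range(n_per_class):
            images.append(_render_class_image(family, level, size, rng))
            labels.append(f"class{c}")
            ids.append(f"class{c}_img{k:03d}")
    spec = {
        "n_classes": n_classes,
        "n_per_class": n_per_class,
        "size": size,
        "seed": seed,
    }
    return SyntheticDataset(images=images, labels=labels, ids=ids, spec=spec)


def add_awgn(
    image: np.ndarray,
    spec: NoiseSpec,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Corrupt one image with zero-mean Gaussian noise, clipped to [0, 255].

    The standard deviation is drawn uniformly from
    ``[sigma_min, sigma_max]``.  Pass an explicit ``rng`` to draw several
    corruptions from one stream; otherwise a fresh generator is seeded from
    ``spec.seed``.
    """
    arr = np.asarray(image, dtype=np.float64)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    sigma = rng.uniform(spec.sigma_min, spec.sigma_max)
    noisy = arr + rng.normal(0.0, sigma, size=arr.shape)
    return np.clip(noisy, 0.0, 255.0)


def build_noisy_query_protocol(
    dataset: SyntheticDataset, spec: NoiseSpec
) -> NoisyQueryProtocol:
    """Clean database + one noisy query per image, labels preserved."""
    rng = np.random.default_rng(spec.seed)
    noisy_images, pairs, qids = [], {}, []
    for img, img_id in zip(dataset.images, dataset.ids):
        noisy_images.append(add_awgn(img, spec, rng=rng))
        qid = f"{img_id}__noisy"
        qids.append(qid)
        pairs[qid] = img_id
    queries = SyntheticDataset(
        images=noisy_images,
        labels=list(dataset.labels),
        ids=qids,
        spec={**dataset.spec, "noise": (spec.sigma_min, spec.sigma_max, spec.seed)},
    )
    return NoisyQueryProtocol(database=dataset, queries=queries, pairs=pairs)
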