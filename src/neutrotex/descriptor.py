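"""Joint-histogram descriptors and the multi-scale feature vector.

Per neutrosophic channel and scale ``r``, the three label maps are reduced
to two 10-by-2 joint histograms — (MsTrP x RiTxP) and (NrTxP x RiTxP) —
flattened with the binary RiTxP label fastest-varying and concatenated to a
40-bin scale descriptor.  The full descriptor concatenates scale-major, then
T, I, F within each scale: ``120 * S`` values for ``S`` scales.

Per-block normalization to probability histograms is the default; raw
counts are available via ``normalize=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .neutrosophic import to_neutrosophic
from .patterns import (
    PatternLabelMap,
    compute_mstrp_map,
    compute_nrtxp_map,
    compute_ritxp_map,
)

#: bins per (primary x RiTxP) joint block
JOINT_BINS = 20
#: bins per scale per neutrosophic channel (two joint blocks)
SCALE_BINS = 40
#: bins per scale over the three neutrosophic channels
BINS_PER_SCALE = 120

CHANNEL_ORDER = ("T", "I", "F")


@dataclass(frozen=True)
class JointHistogram:
    """Flattened 10-by-2 co-occurrence counts of a primary map with RiTxP."""

    counts: np.ndarray
    pixel_count: int
    primary_dim: int = 10
    ri_dim: int = 2

    def __post_init__(self) -> None:
        if self.counts.shape != (self.primary_dim * self.ri_dim,):
            raise ValueError(f"expected {self.primary_dim * self.ri_dim} bins")


@dataclass(frozen=True)
class ScaleDescriptor:
    """40-bin descriptor of one neutrosophic channel at one scale."""

    values: np.ndarray
    r: int
    normalized: bool

    def __post_init__(self) -> None:
        if self.values.shape != (SCALE_BINS,):
            raise ValueError(f"expected {SCALE_BINS} values, got {self.values.shape}")


@dataclass(frozen=True)
class FullDescriptor:
    """Scale- and channel-concatenated feature vector of one image."""

    values: np.ndarray
    scales: tuple
    image_id: str = ""
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.values.shape != (BINS_PER_SCALE * len(self.scales),):
            raise ValueError(
                f"expected {BINS_PER_SCALE * len(self.scales)} values for "
                f"scales {self.scales}, got {self.values.shape}"
            )


def default_scales(shape: Sequence[int]) -> List[int]:
    """Scales 1..9 for images with min side >= 64, otherwise 1..5."""
    return list(range(1, 10)) if min(shape) >= 64 else list(range(1, 6))


def joint_histogram(primary: PatternLabelMap, ri: PatternLabelMap) -> JointHistogram:
    """Joint histogram of a 10-label primary map with the binary RiTxP map.

    Bin index is ``primary_label * 2 + ri_label``; only pixels valid in both
    maps contribute.
    """
    if primary.r != ri.r or primary.labels.shape != ri.labels.shape:
        raise ValueError(
            f"incompatible label maps: scales ({primary.r}, {ri.r}), "
            f"shapes ({primary.labels.shape}, {ri.labels.shape})"
        )
    if ri.kind != "RiTxP":
        raise ValueError(f"second map must be RiTxP, got {ri.kind}")
    mask = primary.valid_mask & ri.valid_mask
    bins = primary.labels[mask] * 2 + ri.labels[mask]
    counts = np.bincount(bins, minlength=JOINT_BINS).astype(np.float64)
    return JointHistogram(counts=counts, pixel_count=int(mask.sum()))


def scale_descriptor(channel: np.ndarray, r: int, normalize: bool = True) -> ScaleDescriptor:
    """40-bin descriptor of one neutrosophic channel at scale ``r``."""
    mstrp = compute_mstrp_map(channel, r)
    nrtxp = compute_nrtxp_map(channel, r)
    ritxp = compute_ritxp_map(channel, r)
    ms = joint_histogram(mstrp, ritxp)
    nr = joint_histogram(nrtxp, ritxp)
    blocks = []
    for h in (ms, nr):
        c = h.counts
        if normalize and h.pixel_count > 0:
            c = c / h.pixel_count
        blocks.append(c)
    return ScaleDescriptor(values=np.concatenate(blocks), r=r, normalized=normalize)


def _validate_scales(shape: Sequence[int], scales: Sequence[int]) -> List[int]:
    out = []
    for r in scales:
        if not isinstance(r, (int, np.integer)) or r < 1:
            raise ValueError(f"scales must be positive integers, got {r!r}")
        if min(shape) < 2 * r + 1:
            raise ValueError(
                f"scale r={r} is too large for image shape {tuple(shape)} "
                f"(needs min side >= {2 * r + 1})"
            )
        out.append(int(r))
    if not out:
        raise ValueError("at least one scale is required")
    return out


def extract_descriptor(
    image: np.ndarray,
    scales: Optional[Sequence[int]] = None,
    w: int = 3,
    normalize: bool = True,
    image_id: str = "",
) -> FullDescriptor:
    """Full multi-scale descriptor of one grayscale image.

    The image is neutrosophic-transformed once; for each scale (in order)
    and each of T, I, F (in that order) the 40-bin scale descriptor is
    appended, giving ``120 * len(scales)`` values.
    """
    arr = np.asarray(image, dtype=np.float64)
    if scales is None:
        scales = default_scales(arr.shape)
    scales = _validate_scales(arr.shape, scales)
    triplet = to_neutrosophic(arr, w=w)
    parts = []
    for r in scales:
        for _, channel in triplet.channels():
            parts.append(scale_descriptor(channel, r, normalize=normalize).values)
    return FullDescriptor(
        values=np.concatenate(parts),
        scales=tuple(scales),
        image_id=image_id,
        normalized=normalize,
    )


def feature_names(scales: Sequence[int]) -> List[str]:
    """Column names ``s{r}_{T|I|F}_{ms|nr}_{p}_{q}`` matching descriptor order."""
    names = []
    for r in scales:
        for ch in CHANNEL_ORDER:
            for block in ("ms", "nr"):
                for p in range(10):
                    for q in range(2):
                        names.append(f"s{r}_{ch}_{block}_{p}_{q}")
    return names


class MsNrRiTxPExtractor(TransformerMixin, BaseEstimator):
    """Transformer turning grayscale images into multi-scale texture descriptors.

    Parameters
    ----------
    w : int, default=3
        Odd window for the neutrosophic local mean.
    scales : sequence of int or None, default=None
        Circular-neighborhood radii.  ``None`` resolves per image size at
        fit time: 1..9 when the min side is >= 64, else 1..5.
    normalize : bool, default=True
        Emit probability histograms (each 20-bin block sums to 1) rather
        than raw counts.

    Attributes
    ----------
    scales_ : tuple of int
        Resolved scales.
    n_features_ : int
        Descriptor length, ``120 * len(scales_)``.

    Examples
    --------
    >>> import numpy as np
    >>> from neutrotex import MsNrRiTxPExtractor
    >>> imgs = [np.random.default_rng(0).uniform(0, 255, (32, 32)) for _ in range(2)]
    >>> X = MsNrRiTxPExtractor().fit_transform(imgs)
    >>> X.shape
    (2, 600)
    """

    def __init__(self, w: int = 3, scales: Optional[Sequence[int]] = None,
                 normalize: bool = True):
        self.w = w
        self.scales = scales
        self.normalize = normalize

    def _image_list(self, X) -> List[np.ndarray]:
        if isinstance(X, np.ndarray) and X.ndim == 3:
            return [X[i] for i in range(X.shape[0])]
        images = [np.asarray(img, dtype=np.float64) for img in X]
        if not images:
            raise ValueError("X must contain at least one image")
        for img in images:
            if img.ndim != 2:
                raise ValueError("every input must be a 2-D grayscale image")
        return images

    def fit(self, X, y=None):
        images = self._image_list(X)
        scales = self.scales if self.scales is not None else default_scales(images[0].shape)
        self.scales_ = tuple(_validate_scales(images[0].shape, scales))
        self.n_features_ = BINS_PER_SCALE * len(self.scales_)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "scales_"):
            raise ValueError("MsNrRiTxPExtractor is not fitted; call fit first")
        images = self._image_list(X)
        rows = [
            extract_descriptor(img, scales=self.scales_, w=self.w,
                               normalize=self.normalize).values
            for img in images
        ]
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        if not hasattr(self, "scales_"):
            raise ValueError("MsNrRiTxPExtractor is not fitted; call fit first")
        return np.asarray(feature_names(self.scales_), dtype=object)
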