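"""Neutrosophic transform of a grayscale image.

A grayscale image ``Z`` is mapped to three membership images:

* truth ``T``: the min-max normalization of the local mean image
  ``Z̄`` (a ``w``-by-``w`` box mean around every pixel),
* indeterminacy ``I``: the min-max normalization of ``δ = |Z − Z̄|``,
* falsity ``F = 1 − T``.

``T`` encodes how bright a pixel's neighborhood is relative to the rest of
the image, ``I`` how much the pixel deviates from its neighborhood (edges,
noise, fine texture), and ``F`` is the complement of ``T``.  All three lie
in ``[0, 1]`` and inherit invariance to affine rescaling of the input
intensities, which is what makes downstream texture patterns comparable
across acquisition settings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Tuple

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: relative threshold below which a min-max denominator counts as degenerate
_DEGENERATE_RTOL = 1e-12


@dataclass(frozen=True)
class NeutrosophicTriplet:
    """The truth / indeterminacy / falsity images of one grayscale image.

    All three arrays share the source image's shape; every pixel lies in
    ``[0, 1]`` and ``F == 1 - T`` elementwise.
    """

    T: np.ndarray
    I: np.ndarray  # noqa: E741 - the field is called I in the neutrosophic literature
    F: np.ndarray
    window_w: int

    def channels(self) -> Iterator[Tuple[str, np.ndarray]]:
        """Yield ``("T", T), ("I", I), ("F", F)`` in canonical order."""
        yield "T", self.T
        yield "I", self.I
        yield "F", self.F

    @property
    def shape(self) -> Tuple[int, int]:
        return self.T.shape


def _validate_window(w: int) -> None:
    if not isinstance(w, (int, np.integer)) or w < 3 or w % 2 == 0:
        raise ValueError(f"window w must be an odd integer >= 3, got {w!r}")


def _validate_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got ndim={arr.ndim}")
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError(f"image must be at least 3x3, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError("image intensities must be finite and non-negative")
    return arr


def local_mean(image: np.ndarray, w: int = 3) -> np.ndarray:
    """``w``-by-``w`` box mean around every pixel, replicate-padded at borders.

    Parameters
    ----------
    image : 2-D array
        Grayscale intensities; promoted to float64.
    w : int
        Odd window side length, >= 3.
    """
    _validate_window(w)
    arr = _validate_image(image)
    return ndimage.uniform_filter(arr, size=w, mode="nearest")


def _minmax(arr: np.ndarray, name: str) -> np.ndarray:
    lo = float(arr.min())
    hi = float(arr.max())
    span = hi - lo
    if span <= _DEGENERATE_RTOL * max(1.0, abs(hi)):
        logger.warning(
            "degenerate %s channel (max - min = %.3g); emitting constant 0", name, span
        )
        return np.zeros_like(arr)
    return (arr - lo) / span


def to_neutrosophic(image: np.ndarray, w: int = 3) -> NeutrosophicTriplet:
    """Transform a grayscale image into its neutrosophic triplet.

    ``T`` is the min-max normalized local-mean image, ``I`` the min-max
    normalized absolute deviation ``|Z - Z̄|`` and ``F = 1 - T``.  A constant
    image (or constant deviation image) makes the min-max denominator vanish;
    the affected channel is then the constant 0 (hence ``F = 1``) and a
    warning is logged.
    """
    arr = _validate_image(image)
    zbar = local_mean(arr, w)
    T = _minmax(zbar, "truth")
    delta = np.abs(arr - zbar)
    I = _minmax(delta, "indeterminacy")  # noqa: E741
    F = 1.0 - T
    return NeutrosophicTriplet(T=T, I=I, F=F, window_w=int(w))
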