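"""Local pattern operators on circular neighborhoods.

At scale ``r`` every pixel ``p_c`` gets a circular neighborhood of ``8r``
samples evenly spaced on the radius-``r`` circle (bilinear interpolation for
off-grid positions).  Three per-pixel label maps are derived from it:

* **MsTrP** - the ``8r`` samples are median-quantized arc-wise down to 8
  values; thresholding them against ``p_c`` gives an 8-bit code that is
  mapped through the rotation-invariant uniform (riu2) relabeling to one of
  10 labels.  The arc-wise median suppresses impulsive outliers, which is
  what makes the code noise-tolerant at larger scales.
* **NrTxP** - absolute differences ``|sample - p_c|`` are mean-quantized
  arc-wise to 8 magnitudes and thresholded against an adaptive ring
  statistic ``nu_r`` (the mean, over the square ring at Chebyshev distance
  ``r``, of the per-pixel mean absolute local difference); riu2-mapped to 10
  labels.
* **RiTxP** - a single bit: is ``p_c`` at least the mean intensity of the
  square ring at Chebyshev distance ``r``.

Labels are defined on the valid region ``[r, M-r) x [r, N-r)`` (0-based);
border pixels carry the sentinel ``-1`` and are excluded from histograms.
The threshold function ``s`` uses ``s(0) = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Tuple

import numpy as np
from scipy import ndimage

#: coordinates within this distance of a grid point snap to the exact pixel
SNAP_TOL = 1e-6

#: slack for the >= 0 threshold so exact ties survive floating-point rounding
SIGN_TOL = 1e-9

PatternKind = Literal["MsTrP", "NrTxP", "RiTxP"]


@dataclass(frozen=True)
class CircularNeighborhood:
    """The ``8r`` circular samples around one center pixel."""

    r: int
    samples: np.ndarray  # shape (8r,)
    center_value: float

    def __post_init__(self) -> None:
        if self.samples.shape != (8 * self.r,):
            raise ValueError(
                f"expected {8 * self.r} samples at r={self.r}, got {self.samples.shape}"
            )


@dataclass(frozen=True)
class PatternLabelMap:
    """Per-pixel integer labels at one scale; ``-1`` marks invalid border pixels."""

    labels: np.ndarray
    kind: PatternKind
    r: int

    @property
    def valid_mask(self) -> np.ndarray:
        return self.labels >= 0

    @property
    def n_labels(self) -> int:
        return 2 if self.kind == "RiTxP" else 10


def circle_offsets(r: int) -> np.ndarray:
    """(row, col) offsets of the ``8r`` samples, n = 0 due east, counter-clockwise.

    Sample ``n`` sits at ``(-r sin θ_n, r cos θ_n)`` with ``θ_n = 2πn / 8r``;
    offsets within :data:`SNAP_TOL` of an integer snap to it.
    """
    if not isinstance(r, (int, np.integer)) or r < 1:
        raise ValueError(f"scale r must be a positive integer, got {r!r}")
    n = np.arange(8 * r, dtype=np.float64)
    theta = 2.0 * np.pi * n / (8.0 * r)
    dy = -r * np.sin(theta)
    dx = r * np.cos(theta)
    dy = np.where(np.abs(dy - np.round(dy)) < SNAP_TOL, np.round(dy), dy)
    dx = np.where(np.abs(dx - np.round(dx)) < SNAP_TOL, np.round(dx), dx)
    return np.stack([dy, dx], axis=1)


def _bilinear_at(image: np.ndarray, y: float, x: float) -> float:
    """Bilinear interpolation with edge clamping at a single point."""
    M, N = image.shape
    y0 = int(np.floor(y))
    x0 = int(np.floor(x))
    ty = y - y0
    tx = x - x0

    def px(i: int, j: int) -> float:
        return float(image[min(max(i, 0), M - 1), min(max(j, 0), N - 1)])

    if ty == 0.0 and tx == 0.0:
        return px(y0, x0)
    return (
        (1 - ty) * (1 - tx) * px(y0, x0)
        + (1 - ty) * tx * px(y0, x0 + 1)
        + ty * (1 - tx) * px(y0 + 1, x0)
        + ty * tx * px(y0 + 1, x0 + 1)
    )


def sample_circle(image: np.ndarray, i: int, j: int, r: int) -> CircularNeighborhood:
    """Sample the ``8r`` circular neighbors of pixel ``(i, j)`` at scale ``r``.

    ``(i, j)`` must lie in the valid region ``[r, M-r) x [r, N-r)`` (0-based).
    """
    arr = np.asarray(image, dtype=np.float64)
    M, N = arr.shape
    if not (r <= i < M - r and r <= j < N - r):
        raise ValueError(
            f"pixel ({i}, {j}) is outside the valid region for r={r} on shape {arr.shape}"
        )
    offs = circle_offsets(r)
    samples = np.array([_bilinear_at(arr, i + dy, j + dx) for dy, dx in offs])
    return CircularNeighborhood(r=r, samples=samples, center_value=float(arr[i, j]))


def median_quantize(nb: CircularNeighborhood) -> np.ndarray:
    """Arc-wise median: 8 values, element ``k`` the median of samples ``rk .. rk+r-1``."""
    return np.median(nb.samples.reshape(8, nb.r), axis=1)


def mean_local_difference_quantize(nb: CircularNeighborhood) -> np.ndarray:
    """Arc-wise mean of ``|sample - center|``: 8 non-negative magnitudes."""
    ld = np.abs(nb.samples - nb.center_value)
    return ld.reshape(8, nb.r).mean(axis=1)


def _validate_bits(bits: np.ndarray) -> np.ndarray:
    arr = np.asarray(bits)
    if arr.shape != (8,):
        raise ValueError(f"expected 8 binary elements, got shape {arr.shape}")
    if not np.all((arr == 0) | (arr == 1)):
        raise ValueError("bit vector elements must be 0 or 1")
    return arr.astype(np.int64)


def uniformity(bits: np.ndarray) -> int:
    """Circular 0/1 transition count of an 8-bit pattern (wraparound included)."""
    b = _validate_bits(bits)
    return int(np.abs(b[0] - b[7]) + np.abs(np.diff(b)).sum())


def riu2_label(bits: np.ndarray) -> int:
    """Rotation-invariant uniform label: popcount if <= 2 transitions, else 9."""
    b = _validate_bits(bits)
    if uniformity(b) <= 2:
        return int(b.sum())
    return 9


# ---------------------------------------------------------------------------
# vectorized full-grid machinery
# ---------------------------------------------------------------------------


def _sample_stack(image: np.ndarray, r: int) -> np.ndarray:
    """Circular samples for every pixel: shape ``(8r, M, N)``, replicate-padded.

    Each sample index has one fixed fractional offset, so the whole grid can
    be sampled with four shifted views of an edge-padded copy of the image.
    """
    arr = np.asarray(image, dtype=np.float64)
    M, N = arr.shape
    pad = r + 1
    P = np.pad(arr, pad, mode="edge")
    offs = circle_offsets(r)
    out = np.empty((8 * r, M, N), dtype=np.float64)
    for idx, (dy, dx) in enumerate(offs):
        y0 = int(np.floor(dy))
        x0 = int(np.floor(dx))
        ty = dy - y0
        tx = dx - x0

        def view(a: int, b: int) -> np.ndarray:
            return P[pad + a : pad + a + M, pad + b : pad + b + N]

        if ty == 0.0 and tx == 0.0:
            out[idx] = view(y0, x0)
        else:
            out[idx] = (
                (1 - ty) * (1 - tx) * view(y0, x0)
                + (1 - ty) * tx * view(y0, x0 + 1)
                + ty * (1 - tx) * view(y0 + 1, x0)
                + ty * tx * view(y0 + 1, x0 + 1)
            )
    return out


def _ring_mean(arr: np.ndarray, r: int) -> np.ndarray:
    """Mean over the ``8r`` pixels of the square ring at Chebyshev distance ``r``.

    Computed as the difference of two box sums; exact (up to rounding) on the
    valid region, where the ring lies fully inside the grid.
    """
    outer = (2 * r + 1) ** 2 * ndimage.uniform_filter(arr, size=2 * r + 1, mode="nearest")
    inner = (2 * r - 1) ** 2 * ndimage.uniform_filter(arr, size=2 * r - 1, mode="nearest")
    return (outer - inner) / (8.0 * r)


def _check_scale(image: np.ndarray, r: int) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got ndim={arr.ndim}")
    if not isinstance(r, (int, np.integer)) or r < 1:
        raise ValueError(f"scale r must be a positive integer, got {r!r}")
    if arr.shape[0] < 2 * r + 1 or arr.shape[1] < 2 * r + 1:
        raise ValueError(
            f"image of shape {arr.shape} is too small for scale r={r} "
            f"(needs at least {2 * r + 1}x{2 * r + 1})"
        )
    return arr


def _riu2_from_bits(bits: np.ndarray) -> np.ndarray:
    """Vectorized riu2 relabeling of a ``(8, M, N)`` boolean bit stack."""
    b = bits.astype(np.int8)
    transitions = np.abs(b[0] - b[7]) + np.abs(np.diff(b, axis=0)).sum(axis=0)
    popcount = b.sum(axis=0)
    return np.where(transitions <= 2, popcount, 9).astype(np.int64)


def _mask_border(labels: np.ndarray, r: int) -> np.ndarray:
    out = np.full_like(labels, -1)
    out[r:-r, r:-r] = labels[r:-r, r:-r]
    return out


def compute_mstrp_map(image: np.ndarray, r: int) -> PatternLabelMap:
    """Median-quantized multi-scale pattern labels (0-9) at scale ``r``."""
    arr = _check_scale(image, r)
    samples = _sample_stack(arr, r)
    mqp = np.median(samples.reshape(8, r, *arr.shape), axis=1)
    bits = (mqp - arr[None]) >= -SIGN_TOL
    labels = _riu2_from_bits(bits)
    return PatternLabelMap(labels=_mask_border(labels, r), kind="MsTrP", r=r)


def compute_nrtxp_map(image: np.ndarray, r: int) -> PatternLabelMap:
    """Noise-resistant local-difference pattern labels (0-9) at scale ``r``.

    The per-pixel mean absolute local difference image is computed on the
    full grid (replicate-padded sampling) so the adaptive ring threshold
    ``nu_r`` is defined everywhere in the valid region.
    """
    arr = _check_scale(image, r)
    samples = _sample_stack(arr, r)
    ld = np.abs(samples - arr[None])
    mldqp = ld.reshape(8, r, *arr.shape).mean(axis=1)
    muld = ld.mean(axis=0)
    nu = _ring_mean(muld, r)
    bits = (mldqp - nu[None]) >= -SIGN_TOL
    labels = _riu2_from_bits(bits)
    return PatternLabelMap(labels=_mask_border(labels, r), kind="NrTxP", r=r)


def compute_ritxp_map(image: np.ndarray, r: int) -> PatternLabelMap:
    """Binary center-vs-ring-mean labels at scale ``r``."""
    arr = _check_scale(image, r)
    mu = _ring_mean(arr, r)
    labels = ((arr - mu) >= -SIGN_TOL).astype(np.int64)
    return PatternLabelMap(labels=_mask_border(labels, r), kind="RiTxP", r=r)
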