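"""Seed-driven adaptive thresholding of wavelet sub-bands.

The low-frequency band carries the organ's identity: a two-class iterative
mean clustering (Ridler-Calvard / ISODATA style), initialized from the pixel
statistics around a user-chosen seed point, yields the low-band threshold
``T_L``.  The high-frequency bands carry edges plus noise: they are denoised
with a Lee filter (a local linear minimum mean-square-error estimator, chosen
for its edge-preserving behaviour) and then hard-thresholded at
``T_H = c * sigma_hat``, where ``sigma_hat`` is a robust noise-level estimate
from the finest diagonal band.

All window statistics use the population (divide-by-N) variance, and windows
are clipped at the image border rather than padded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .filterbank import SubbandSet

__all__ = [
    "SeedPoint",
    "SeedStats",
    "ThresholdPair",
    "LeeParams",
    "collect_seed_stats",
    "compute_low_threshold",
    "apply_low_threshold",
    "estimate_noise_sigma",
    "lee_filter",
    "apply_high_threshold",
]

# MAD of a zero-mean Gaussian is 0.6745 * sigma
_MAD_TO_SIGMA = 0.6744897501960817


@dataclass(frozen=True)
class SeedPoint:
    """A pixel inside the structure of interest, 0-based row/column indices."""

    row: int
    col: int


@dataclass(frozen=True)
class SeedStats:
    """Intensity statistics collected in a window around the seed."""

    mean: float
    variance: float
    sample_size: int

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValidationError("variance must be non-negative")
        if self.sample_size < 1:
            raise ValidationError("sample_size must be at least 1")


@dataclass(frozen=True)
class ThresholdPair:
    """The adaptive thresholds: ``t_low`` on the low band (intensity scale),
    ``t_high`` on the high bands (coefficient-magnitude scale)."""

    t_low: float
    t_high: float

    def __post_init__(self) -> None:
        if self.t_high < 0:
            raise ValidationError("t_high must be non-negative")


@dataclass(frozen=True)
class LeeParams:
    """Lee-filter parameters: local window radius, noise standard deviation,
    and the multiplier ``c`` in ``T_H = c * sigma``."""

    window_radius: int = 1
    noise_sigma: float = 0.0
    threshold_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if self.window_radius < 1:
            raise ValidationError("window_radius must be >= 1")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.threshold_multiplier <= 0:
            raise ValidationError("threshold_multiplier must be > 0")


def _check_seed(image: np.ndarray, seed: SeedPoint) -> None:
    if not (0 <= seed.row < image.shape[0] and 0 <= seed.col < image.shape[1]):
        raise IndexError(
            f"seed ({seed.row}, {seed.col}) outside image of shape {image.shape}"
        )


def collect_seed_stats(
    image: np.ndarray, seed: SeedPoint, window_radius: int = 1
) -> SeedStats:
    """Mean and population variance over the (2r+1)^2 window at the seed.

    The window is intersected with the image, so near a border the sample
    size shrinks (a corner seed with radius 1 sees 4 pixels).
    """
    img = np.asarray(image, dtype=float)
    _check_seed(img, seed)
    if window_radius < 1:
        raise ValidationError("window_radius must be >= 1")
    r0 = max(0, seed.row - window_radius)
    r1 = min(img.shape[0], seed.row + window_radius + 1)
    c0 = max(0, seed.col - window_radius)
    c1 = min(img.shape[1], seed.col + window_radius + 1)
    window = img[r0:r1, c0:c1]
    return SeedStats(
        mean=float(window.mean()),
        variance=float(window.var()),
        sample_size=int(window.size),
    )


def compute_low_threshold(
    low_band: np.ndarray,
    seed_stats: SeedStats,
    *,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> float:
    """Two-class iterative-mean clustering threshold on the low band.

    Class A starts at the seed-window mean; class B starts at the mean of
    the pixels lying farther from the seed mean than the global mean does.
    Pixels are re-assigned to the nearest class mean and the means updated
    until both move by less than ``tol`` (or ``max_iter`` sweeps); the
    threshold is the midpoint of the converged class means.  The procedure
    is equivariant under increasing affine intensity maps.

    Raises
    ------
    DegenerateInputError
        If the band is constant (no two classes exist).
    """
    values = np.asarray(low_band, dtype=float).ravel()
    if values.size == 0 or not np.all(np.isfinite(values)):
        raise ValidationError("low band must be non-empty and finite")
    if values.max() == values.min():
        raise DegenerateInputError("constant band: no two intensity classes exist")

    mean_a = float(seed_stats.mean)
    global_mean = float(values.mean())
    far = values[np.abs(values - mean_a) > abs(global_mean - mean_a)]
    if far.size:
        mean_b = float(far.mean())
    else:
        mean_b = float(values[np.argmax(np.abs(values - mean_a))])
    if mean_b == mean_a:
        mean_b = float(values[np.argmax(np.abs(values - mean_a))])
    if mean_b == mean_a:
        raise DegenerateInputError("could not initialize two distinct classes")

    for _ in range(max_iter):
        in_a = np.abs(values - mean_a) <= np.abs(values - mean_b)
        new_a = float(values[in_a].mean()) if in_a.any() else mean_a
        new_b = float(values[~in_a].mean()) if (~in_a).any() else mean_b
        shift = max(abs(new_a - mean_a), abs(new_b - mean_b))
        mean_a, mean_b = new_a, new_b
        if shift < tol:
            break
    return 0.5 * (mean_a + mean_b)


def apply_low_threshold(
    low_band: np.ndarray, t_low: float, seed: SeedPoint
) -> np.ndarray:
    """Binary indicator of the seed's side of ``t_low``.

    Pixels on the same side of the threshold as the seed's low-band value are
    labeled 1.  A seed value exactly at ``t_low`` counts as above.
    """
    band = np.asarray(low_band, dtype=float)
    _check_seed(band, seed)
    if not np.isfinite(t_low):
        raise ValidationError("t_low must be finite")
    seed_above = band[seed.row, seed.col] >= t_low
    mask = band >= t_low if seed_above else band < t_low
    return mask.astype(np.uint8)


def estimate_noise_sigma(high_bands: "SubbandSet | np.ndarray") -> float:
    """Robust noise level: ``median(|w|) / 0.6745`` on the finest diagonal band.

    Accepts either a full :class:`SubbandSet` (band ``(1, 1)`` is used) or a
    single coefficient plane.  An all-zero band gives 0.
    """
    if isinstance(high_bands, SubbandSet):
        band = high_bands[(1, 1)]
    else:
        band = np.asarray(high_bands, dtype=float)
    return float(np.median(np.abs(band)) / _MAD_TO_SIGMA)


def _shifted_accumulate(padded: np.ndarray, shape, size: int) -> np.ndarray:
    # row-major sequential accumulation: per pixel this adds the window
    # elements one by one, matching a per-pixel hand evaluation bit for bit
    out = np.zeros(shape, dtype=float)
    for di in range(size):
        for dj in range(size):
            out += padded[di : di + shape[0], dj : dj + shape[1]]
    return out


def _window_sums(values: np.ndarray, radius: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Clipped-window sums of values, squares and counts via zero padding."""
    size = 2 * radius + 1
    padded = np.pad(values, radius, mode="constant")
    sums = _shifted_accumulate(padded, values.shape, size)
    sqsums = _shifted_accumulate(padded**2, values.shape, size)
    counts = _shifted_accumulate(
        np.pad(np.ones_like(values), radius, mode="constant"), values.shape, size
    )
    return sums, sqsums, counts


def lee_filter(band: np.ndarray, params: LeeParams) -> np.ndarray:
    """Local linear MMSE (Lee) estimate of each coefficient.

    Per pixel, with clipped-window mean ``m`` and population variance ``v``:
    gain ``k = max(0, v - sigma_n^2) / v`` (``k = 0`` where ``v = 0``) and
    output ``m + k (w - m)``.  With ``sigma_n = 0`` this is the identity; on
    locally constant regions it returns the local mean.
    """
    w = np.asarray(band, dtype=float)
    if w.ndim != 2:
        raise ValidationError("expected a 2D band")
    if not np.all(np.isfinite(w)):
        raise ValidationError("band contains non-finite values")
    if params.noise_sigma == 0:
        # k = 1 wherever v > 0 and w = m wherever v = 0: the exact identity
        return w.copy()
    sums, sqsums, counts = _window_sums(w, params.window_radius)
    m = sums / counts
    v = sqsums / counts - m**2
    v = np.maximum(v, 0.0)  # guard tiny negative round-off
    noise_var = params.noise_sigma**2
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(v > 0, np.maximum(v - noise_var, 0.0) / np.where(v > 0, v, 1.0), 0.0)
    return m + k * (w - m)


def apply_high_threshold(band: np.ndarray, t_high: float) -> np.ndarray:
    """Hard threshold: zero coefficients with ``|w| < t_high``, keep the rest."""
    if t_high < 0:
        raise ValidationError("t_high must be non-negative")
    w = np.asarray(band, dtype=float)
    return np.where(np.abs(w) < t_high, 0.0, w)
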