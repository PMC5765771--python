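"""Undecimated three-channel double-Haar filter bank (1D and separable 2D).

The double-Haar wavelet transform (DHWT) splits a signal into one low-frequency
channel and two high-frequency channels through a three-channel
perfect-reconstruction filter bank built from cascaded Haar filters.  The
moving-window realization used here keeps every channel at the input length
(no subsampling), so a 3-tap bank applied separably along rows and columns is
exactly a 3x3 moving-window transform of the image.

Analysis and synthesis are centered correlations with half-sample symmetric
boundary extension.  Synthesis extends each channel with the parity of its
analysis filter (even for the symmetric ``h0``/``h2`` channels, odd for the
antisymmetric ``h1`` channel); with that convention the round trip is an exact
identity, boundaries included, and the low band preserves the image mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterator, NamedTuple, Sequence, Tuple

import numpy as np

from .errors import ValidationError

__all__ = [
    "FilterBank",
    "Channels1D",
    "SubbandSet",
    "double_haar_bank",
    "analyze_1d",
    "synthesize_1d",
    "analyze_2d",
    "synthesize_2d",
]


class Channels1D(NamedTuple):
    """The three same-length channels of a 1D analysis: low, first high, second high."""

    x0: np.ndarray
    x1: np.ndarray
    x2: np.ndarray


@dataclass(frozen=True)
class FilterBank:
    """A three-channel analysis/synthesis bank with a pure-delay composite response.

    Parameters
    ----------
    analysis_taps : three tap arrays ``(h0, h1, h2)``; ``h0`` is low-pass
        (taps sum to 1), ``h1`` and ``h2`` are high-pass (taps sum to 0).
    synthesis_taps : three tap arrays ``(g0, g1, g2)``.
    delay : delay, in samples, of the causal composite
        ``sum_i g_i * h_i`` (compensated internally by center alignment).
    """

    analysis_taps: Tuple[np.ndarray, np.ndarray, np.ndarray]
    synthesis_taps: Tuple[np.ndarray, np.ndarray, np.ndarray]
    delay: int

    def __post_init__(self) -> None:
        a = tuple(np.asarray(t, dtype=float) for t in self.analysis_taps)
        s = tuple(np.asarray(t, dtype=float) for t in self.synthesis_taps)
        object.__setattr__(self, "analysis_taps", a)
        object.__setattr__(self, "synthesis_taps", s)
        if len(a) != 3 or len(s) != 3:
            raise ValidationError("a filter bank has exactly three channels")
        if abs(a[0].sum() - 1.0) > 1e-12:
            raise ValidationError("low-pass taps h0 must sum to 1")
        for i in (1, 2):
            if abs(a[i].sum()) > 1e-12:
                raise ValidationError(f"high-pass taps h{i} must sum to 0")
        err = self.reconstruction_defect()
        if err > 1e-12:
            raise ValidationError(
                f"bank is not perfect-reconstruction: composite deviates from "
                f"a pure delay by {err:.3e}"
            )

    def reconstruction_defect(self) -> float:
        """Max deviation of ``sum_i g_i * h_i`` from a unit impulse at ``delay``."""
        n = max(
            len(g) + len(h) - 1
            for g, h in zip(self.synthesis_taps, self.analysis_taps)
        )
        total = np.zeros(n)
        for g, h in zip(self.synthesis_taps, self.analysis_taps):
            c = np.convolve(g, h)
            total[: len(c)] += c
        ideal = np.zeros(n)
        ideal[self.delay] = 1.0
        return float(np.abs(total - ideal).max())

    def channel_parity(self, i: int) -> int:
        """+1 if analysis filter ``i`` is symmetric, -1 if antisymmetric."""
        h = self.analysis_taps[i]
        if np.array_equal(h, h[::-1]):
            return 1
        if np.array_equal(h, -h[::-1]):
            return -1
        raise ValidationError(f"analysis filter h{i} has no reflection symmetry")

    @property
    def support(self) -> int:
        return max(len(t) for t in self.analysis_taps + self.synthesis_taps)


def double_haar_bank() -> FilterBank:
    """The default double-Haar bank: products of two Haar stages, 3 taps each.

    Analysis ``h0 = [1,2,1]/4`` (smoother), ``h1 = [1,0,-1]/2`` (first
    difference), ``h2 = [1,-2,1]/4`` (second difference); synthesis
    ``g0 = [1,2,1]/4``, ``g1 = [-1,0,1]/4``, ``g2 = [1,-2,1]/4``.  The
    composite ``sum_i g_i h_i`` is a pure 2-sample delay.
    """
    return FilterBank(
        analysis_taps=(
            np.array([1.0, 2.0, 1.0]) / 4.0,
            np.array([1.0, 0.0, -1.0]) / 2.0,
            np.array([1.0, -2.0, 1.0]) / 4.0,
        ),
        synthesis_taps=(
            np.array([1.0, 2.0, 1.0]) / 4.0,
            np.array([-1.0, 0.0, 1.0]) / 4.0,
            np.array([1.0, -2.0, 1.0]) / 4.0,
        ),
        delay=2,
    )


def _pad_axis(a: np.ndarray, radius: int, axis: int, parity: int) -> np.ndarray:
    """Half-sample symmetric padding along ``axis``; odd parity negates the flaps."""
    width = [(0, 0)] * a.ndim
    width[axis] = (radius, radius)
    padded = np.pad(a, width, mode="symmetric")
    if parity < 0:
        lo = [slice(None)] * a.ndim
        hi = [slice(None)] * a.ndim
        lo[axis] = slice(0, radius)
        hi[axis] = slice(padded.shape[axis] - radius, padded.shape[axis])
        padded[tuple(lo)] = -padded[tuple(lo)]
        padded[tuple(hi)] = -padded[tuple(hi)]
    return padded


def _correlate_axis(
    a: np.ndarray, taps: np.ndarray, axis: int, parity: int = 1
) -> np.ndarray:
    """Centered correlation with ``taps`` along one axis, boundary-extended."""
    radius = len(taps) // 2
    padded = _pad_axis(np.asarray(a, dtype=float), radius, axis, parity)
    out = np.zeros(a.shape, dtype=float)
    index: list = [slice(None)] * a.ndim
    for k, t in enumerate(taps):
        index[axis] = slice(k, k + a.shape[axis])
        out += t * padded[tuple(index)]
    return out


def _validate_signal(signal: np.ndarray, bank: FilterBank) -> np.ndarray:
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValidationError("expected a 1D signal")
    if x.size < bank.support:
        raise ValidationError(
            f"signal of length {x.size} is shorter than the filter support "
            f"({bank.support})"
        )
    if not np.all(np.isfinite(x)):
        raise ValidationError("signal contains non-finite values")
    return x


def analyze_1d(signal: Sequence[float], bank: FilterBank | None = None) -> Channels1D:
    """Split a 1D signal into the three undecimated channels.

    Each channel is the centered correlation of the half-sample symmetric
    extension of ``signal`` with the corresponding analysis taps, so every
    channel has the length of the input.
    """
    bank = bank or double_haar_bank()
    x = _validate_signal(signal, bank)
    return Channels1D(*(_correlate_axis(x, h, axis=0) for h in bank.analysis_taps))


def synthesize_1d(channels: Channels1D, bank: FilterBank | None = None) -> np.ndarray:
    """Recombine three channels into a signal (exact inverse of :func:`analyze_1d`).

    Each channel is extended with the parity of its analysis filter and
    correlated with the matching synthesis taps; the results are summed.
    """
    bank = bank or double_haar_bank()
    arrays = [np.asarray(c, dtype=float) for c in channels]
    if len(arrays) != 3 or any(c.shape != arrays[0].shape for c in arrays):
        raise ValidationError("expected three equal-length channels")
    out = np.zeros(arrays[0].shape, dtype=float)
    for i, (c, g) in enumerate(zip(arrays, bank.synthesis_taps)):
        out += _correlate_axis(c, g, axis=0, parity=bank.channel_parity(i))
    return out


class SubbandSet:
    """Nine same-shaped coefficient planes from separable 2D analysis.

    Band ``(r, c)`` is the result of analysis filter ``h_r`` applied along
    rows (axis 0) then ``h_c`` along columns (axis 1).  Band ``(0, 0)`` is
    the low-frequency component; the other eight are high-frequency.
    """

    def __init__(self, bands: Dict[Tuple[int, int], np.ndarray]):
        keys = {(r, c) for r in range(3) for c in range(3)}
        if set(bands) != keys:
            raise ValidationError("a SubbandSet requires exactly the 9 bands (r,c) in {0,1,2}^2")
        shape = bands[(0, 0)].shape
        for key, band in bands.items():
            band = np.asarray(band, dtype=float)
            if band.shape != shape:
                raise ValidationError(f"band {key} has shape {band.shape}, expected {shape}")
            bands[key] = band
        self.bands = bands
        self.shape = shape

    def __getitem__(self, key: Tuple[int, int]) -> np.ndarray:
        return self.bands[key]

    def __setitem__(self, key: Tuple[int, int], value: np.ndarray) -> None:
        value = np.asarray(value, dtype=float)
        if value.shape != self.shape:
            raise ValidationError("replacement band has the wrong shape")
        self.bands[key] = value

    @property
    def low(self) -> np.ndarray:
        return self.bands[(0, 0)]

    def high_items(self) -> Iterator[Tuple[Tuple[int, int], np.ndarray]]:
        """Iterate over the 8 high-frequency bands in fixed (row, col) order."""
        for r in range(3):
            for c in range(3):
                if (r, c) != (0, 0):
                    yield (r, c), self.bands[(r, c)]

    def copy(self) -> "SubbandSet":
        return SubbandSet({k: v.copy() for k, v in self.bands.items()})


def _validate_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValidationError("expected a 2D image")
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValidationError("image must be at least 3x3")
    if not np.all(np.isfinite(img)):
        raise ValidationError("image contains non-finite pixels")
    return img


def analyze_2d(image: np.ndarray, bank: FilterBank | None = None) -> SubbandSet:
    """Separable 2D analysis: nine undecimated sub-bands of the image.

    With the default 3-tap bank this is exactly a 3x3 moving-window
    transform: band ``(r, c)`` equals the windowed dot product of the
    boundary-extended image with the tensor-product mask ``outer(h_r, h_c)``.
    """
    bank = bank or double_haar_bank()
    img = _validate_image(image)
    rows = [_correlate_axis(img, h, axis=0) for h in bank.analysis_taps]
    bands = {
        (r, c): _correlate_axis(rows[r], h, axis=1)
        for r in range(3)
        for c, h in enumerate(bank.analysis_taps)
    }
    return SubbandSet(bands)


def synthesize_2d(bands: SubbandSet, bank: FilterBank | None = None) -> np.ndarray:
    """Separable 2D synthesis; linear in the bands and the exact inverse of
    :func:`analyze_2d` when the bands are untouched."""
    bank = bank or double_haar_bank()
    if not isinstance(bands, SubbandSet):
        bands = SubbandSet(dict(bands))
    out = np.zeros(bands.shape, dtype=float)
    for r in range(3):
        for c in range(3):
            partial = _correlate_axis(
                bands[(r, c)], bank.synthesis_taps[r], axis=0,
                parity=bank.channel_parity(r),
            )
            out += _correlate_axis(
                partial, bank.synthesis_taps[c], axis=1,
                parity=bank.channel_parity(c),
            )
    return out
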