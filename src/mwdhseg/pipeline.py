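"""End-to-end seeded wavelet-domain segmentation of a slice or a stack.

The pipeline follows the method's flow: three-channel moving-window
double-Haar analysis of the slice; seed statistics collected on the
low-frequency band; a cluster-based threshold ``T_L`` classifies the low band
into the seed's intensity class versus the rest; the eight high-frequency
bands are Lee-filtered and hard-thresholded at ``T_H``; wavelet synthesis of
the modified coefficients yields a near-two-level reconstruction that is
binarized and post-processed (seed connected component, hole filling) into
the final mask.

The low band is replaced by a two-level image taking the seed-class mean on
the seed class and the complement-class mean elsewhere, and the
reconstruction is binarized at ``bg + binarize_level * (obj - bg)``.  Because
both levels and the cut move with the data, the mask is invariant under
constant intensity shifts and handles objects darker than their surroundings
without special-casing.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, SegmentationEmptyError, ValidationError
from .filterbank import FilterBank, analyze_2d, double_haar_bank, synthesize_2d
from .thresholding import (
    LeeParams,
    SeedPoint,
    ThresholdPair,
    apply_high_threshold,
    apply_low_threshold,
    collect_seed_stats,
    compute_low_threshold,
    estimate_noise_sigma,
    lee_filter,
)

__all__ = [
    "PipelineConfig",
    "SegmentationResult",
    "segment_slice",
    "postprocess_mask",
    "segment_volume",
]

# 4-connectivity for object components, 8-connectivity for hole filling
_COMPONENT_STRUCTURE = ndimage.generate_binary_structure(2, 1)
_HOLE_STRUCTURE = np.ones((3, 3), dtype=bool)

# a propagated slice whose mask balloons past this factor of its neighbour is
# treated as a failed (background-grabbing) segmentation
_PROPAGATION_AREA_LIMIT = 8.0


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the segmentation pipeline.

    The 3x3 defaults (radius 1) for both the seed-statistics window and the
    Lee window match the moving-window size of the transform itself.
    ``threshold_multiplier`` is the ``c`` in ``T_H = c * sigma_hat`` (3 is
    the standard detection threshold).  ``binarize_level`` places the final
    cut between the background-class and object-class levels of the
    reconstruction (0.5 = midpoint; ties count as foreground).
    """

    stats_window_radius: int = 1
    lee_window_radius: int = 1
    threshold_multiplier: float = 3.0
    binarize_level: float = 0.5
    keep_seed_component: bool = True
    fill_holes: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.stats_window_radius < 1 or self.lee_window_radius < 1:
            raise ValidationError("window radii must be >= 1")
        if self.threshold_multiplier <= 0:
            raise ValidationError("threshold_multiplier must be > 0")
        if not 0 < self.binarize_level < 1:
            raise ValidationError("binarize_level must be in (0, 1)")


@dataclass
class SegmentationResult:
    """A binary mask plus the thresholds, the pre-binarization reconstruction
    and the provenance (config and seed) that produced it."""

    mask: np.ndarray
    thresholds: ThresholdPair
    reconstructed: np.ndarray
    provenance: Dict = field(default_factory=dict)


def postprocess_mask(
    mask: np.ndarray, seed: SeedPoint, config: PipelineConfig
) -> np.ndarray:
    """Keep the seed's 4-connected component and fill enclosed holes.

    Raises :class:`SegmentationEmptyError` if the seed pixel is not in the
    mask — the segmentation found no object at the seed.
    """
    m = np.asarray(mask).astype(bool)
    if not m[seed.row, seed.col]:
        raise SegmentationEmptyError(
            f"segmentation empty at seed ({seed.row}, {seed.col})"
        )
    if config.keep_seed_component:
        labels, _ = ndimage.label(m, structure=_COMPONENT_STRUCTURE)
        m = labels == labels[seed.row, seed.col]
    if config.fill_holes:
        m = ndimage.binary_fill_holes(m, structure=_HOLE_STRUCTURE)
    return m.astype(np.uint8)


def segment_slice(
    image: np.ndarray,
    seed: SeedPoint,
    config: Optional[PipelineConfig] = None,
    bank: Optional[FilterBank] = None,
) -> SegmentationResult:
    """Segment the structure containing ``seed`` in a single 2D slice.

    Raises
    ------
    DegenerateInputError
        For a constant image (no intensity classes to separate).
    IndexError
        For a seed outside the image.
    SegmentationEmptyError
        If binarization leaves the seed pixel unlabeled.
    """
    config = config or PipelineConfig()
    bank = bank or double_haar_bank()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValidationError("expected a 2D slice")
    if not np.all(np.isfinite(img)):
        raise ValidationError("image contains non-finite pixels")
    if not (0 <= seed.row < img.shape[0] and 0 <= seed.col < img.shape[1]):
        raise IndexError(f"seed ({seed.row}, {seed.col}) outside image {img.shape}")
    if img.max() == img.min():
        raise DegenerateInputError("constant image cannot be segmented")

    bands = analyze_2d(img, bank)
    low = bands.low

    stats = collect_seed_stats(low, seed, config.stats_window_radius)
    t_low = compute_low_threshold(low, stats)
    indicator = apply_low_threshold(low, t_low, seed).astype(bool)
    if indicator.all() or not indicator.any():
        raise DegenerateInputError("low-band threshold produced a single class")
    object_level = float(low[indicator].mean())
    background_level = float(low[~indicator].mean())

    sigma = estimate_noise_sigma(bands)
    t_high = config.threshold_multiplier * sigma
    lee = LeeParams(
        window_radius=config.lee_window_radius,
        noise_sigma=sigma,
        threshold_multiplier=config.threshold_multiplier,
    )
    modified = bands.copy()
    modified[(0, 0)] = np.where(indicator, object_level, background_level)
    for key, band in bands.high_items():
        modified[key] = apply_high_threshold(lee_filter(band, lee), t_high)

    reconstructed = synthesize_2d(modified, bank)
    span = object_level - background_level
    cut = background_level + config.binarize_level * span
    if span >= 0:
        raw_mask = reconstructed >= cut  # tie counts as foreground
    else:
        raw_mask = reconstructed <= cut
    mask = postprocess_mask(raw_mask, seed, config)

    return SegmentationResult(
        mask=mask,
        thresholds=ThresholdPair(t_low=float(t_low), t_high=float(t_high)),
        reconstructed=reconstructed,
        provenance={
            "seed": {"row": seed.row, "col": seed.col},
            "config": asdict(config),
            "object_level": object_level,
            "background_level": background_level,
            "noise_sigma": sigma,
        },
    )


def _empty_like(img: np.ndarray) -> np.ndarray:
    return np.zeros(np.asarray(img).shape, dtype=np.uint8)


def segment_volume(
    slices: Sequence[np.ndarray],
    seed: SeedPoint,
    config: Optional[PipelineConfig] = None,
    *,
    seed_slice: int = 0,
    bank: Optional[FilterBank] = None,
) -> List[np.ndarray]:
    """Segment a stack slice-by-slice, propagating the seed by mask centroid.

    The seed slice is segmented first; each neighbouring slice then reuses
    the rounded centroid of the previous slice's mask as its seed.  A
    direction stops propagating when a slice fails (empty result, degenerate
    slice, propagated centroid on background, or a mask that balloons past
    ``_PROPAGATION_AREA_LIMIT`` times its neighbour's area, which signals a
    background grab); the remaining masks in that direction are empty.
    """
    config = config or PipelineConfig()
    if len(slices) == 0:
        raise ValidationError("need at least one slice")
    shapes = {np.asarray(s).shape for s in slices}
    if len(shapes) != 1:
        raise ValidationError("all slices must share one shape")
    if not 0 <= seed_slice < len(slices):
        raise IndexError(f"seed_slice {seed_slice} outside stack of {len(slices)}")

    masks: List[np.ndarray] = [_empty_like(s) for s in slices]
    first = segment_slice(slices[seed_slice], seed, config, bank)
    masks[seed_slice] = first.mask

    for step in (1, -1):
        prev_mask = first.mask
        index = seed_slice + step
        while 0 <= index < len(slices):
            rows, cols = np.nonzero(prev_mask)
            next_seed = SeedPoint(int(round(rows.mean())), int(round(cols.mean())))
            try:
                result = segment_slice(slices[index], next_seed, config, bank)
            except (SegmentationEmptyError, DegenerateInputError):
                break
            if result.mask.sum() > _PROPAGATION_AREA_LIMIT * max(prev_mask.sum(), 1):
                break
            masks[index] = result.mask
            prev_mask = result.mask
            index += step
    return masks
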