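"""Synthetic pelvic-CBCT phantom with ground truth and beacon artifacts.

Patient CBCT cannot be redistributed, so this module generates controlled
stand-ins at desk scale: three elliptical soft-tissue "organs" (bladder,
prostate, rectum) at distinct mean intensities over a uniform background,
per-pixel Gaussian noise, optional implanted-transponder artifacts (small
high-intensity discs with radially decaying, alternating-sign streaks — the
qualitative signature of metal in CBCT), and an optional low-intensity gas
pocket inside the rectum.

Ground-truth masks are the analytic point-in-ellipse memberships of the
noise-free geometry; suggested seed points are the organ centroids.  Every
image is deterministic given ``rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Iterator, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .thresholding import SeedPoint

__all__ = [
    "OrganSpec",
    "BeaconSpec",
    "PhantomSpec",
    "PhantomCase",
    "ellipse_mask",
    "generate_phantom",
    "add_beacon_artifacts",
    "default_scenarios",
]


@dataclass(frozen=True)
class OrganSpec:
    """An elliptical organ: geometry in pixels plus mean intensity.

    ``texture_sigma`` adds organ-specific intensity texture on top of the
    global image noise (0 = perfectly uniform tissue).
    """

    name: str
    center: Tuple[float, float]  # (row, col)
    axes: Tuple[float, float]  # semi-axes (row, col) before rotation
    mean_intensity: float
    rotation: float = 0.0  # radians, counter-clockwise
    texture_sigma: float = 0.0

    def __post_init__(self) -> None:
        if min(self.axes) <= 0:
            raise ValidationError(f"organ {self.name}: axes must be positive")
        if self.texture_sigma < 0:
            raise ValidationError(f"organ {self.name}: texture_sigma must be >= 0")


@dataclass(frozen=True)
class BeaconSpec:
    """A metal transponder: bright disc plus radial streak artifacts."""

    center: Tuple[int, int]  # (row, col)
    radius: float = 2.0
    peak_intensity: float = 400.0
    streak_count: int = 8
    streak_amplitude: float = 25.0
    streak_decay: float = 0.06  # per-pixel exponential decay rate

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValidationError("beacon radius must be >= 1")
        if self.streak_count < 0:
            raise ValidationError("streak_count must be >= 0")
        if self.streak_decay <= 0:
            raise ValidationError("streak_decay must be > 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic slice."""

    shape: Tuple[int, int] = (192, 192)
    background_intensity: float = 80.0
    noise_sigma: float = 6.0
    organs: Tuple[OrganSpec, ...] = ()
    beacons: Tuple[BeaconSpec, ...] = ()
    gas_fraction: float = 0.0  # fraction of rectum area replaced by gas
    gas_intensity: float = 5.0  # near the background minimum
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if not 0 <= self.gas_fraction < 1:
            raise ValidationError("gas_fraction must be in [0, 1)")
        object.__setattr__(self, "organs", tuple(self.organs))
        object.__setattr__(self, "beacons", tuple(self.beacons))


@dataclass(frozen=True)
class PhantomCase:
    """A generated slice with its analytic ground truth and suggested seeds."""

    image: np.ndarray
    truth_masks: Dict[str, np.ndarray]
    suggested_seeds: Dict[str, SeedPoint]
    spec: PhantomSpec


def ellipse_mask(
    shape: Tuple[int, int],
    center: Tuple[float, float],
    axes: Tuple[float, float],
    rotation: float = 0.0,
) -> np.ndarray:
    """Boolean point-in-ellipse membership on a pixel grid."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    cos_t, sin_t = math.cos(rotation), math.sin(rotation)
    u = cos_t * dr + sin_t * dc
    v = -sin_t * dr + cos_t * dc
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _ray_pixels(
    center: Tuple[int, int], angle: float, shape: Tuple[int, int]
) -> Iterator[Tuple[int, int, int]]:
    """Pixels (row, col, step) along a half-line from the center, unit steps.

    Each pixel is yielded once (consecutive unit steps may round to the same
    pixel; the first step wins).  Shared by the generator and by anyone
    sampling a streak profile, so the two rasterizations agree exactly.
    """
    dr, dc = math.sin(angle), math.cos(angle)
    max_steps = int(math.hypot(*shape)) + 2
    seen = set()
    for t in range(1, max_steps):
        r = int(round(center[0] + t * dr))
        c = int(round(center[1] + t * dc))
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            return
        if (r, c) in seen:
            continue
        seen.add((r, c))
        yield r, c, t


def streak_perturbation(amplitude: float, decay: float, step: int) -> float:
    """Signed streak intensity at ``step`` pixels from the beacon center:
    alternating sign under the envelope ``amplitude * exp(-step * decay)``."""
    return (-1.0) ** step * amplitude * math.exp(-step * decay)


def add_beacon_artifacts(
    image: np.ndarray,
    beacons: Sequence[BeaconSpec],
    rng: np.random.Generator,
) -> np.ndarray:
    """Stamp transponder artifacts onto a copy of the image.

    For each beacon, ``streak_count`` rays leave the center at evenly spaced
    angles with a common random offset; each ray adds an alternating-sign
    perturbation with envelope ``streak_amplitude * exp(-d * streak_decay)``.
    Disc pixels (within ``radius`` of the center) are set to
    ``peak_intensity`` after all streaks, so every disc pixel ends at least
    at its peak value.
    """
    out = np.asarray(image, dtype=float).copy()
    shape = out.shape
    for b in beacons:
        if not (0 <= b.center[0] < shape[0] and 0 <= b.center[1] < shape[1]):
            raise ValidationError(f"beacon center {b.center} outside image {shape}")
    for b in beacons:
        if b.streak_count == 0:
            continue
        offset = rng.uniform(0.0, 2.0 * math.pi)
        for i in range(b.streak_count):
            angle = offset + 2.0 * math.pi * i / b.streak_count
            for r, c, t in _ray_pixels(b.center, angle, shape):
                out[r, c] += streak_perturbation(b.streak_amplitude, b.streak_decay, t)
    for b in beacons:
        disc = ellipse_mask(shape, b.center, (b.radius, b.radius))
        out[disc] = b.peak_intensity
    return out


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Render a phantom slice: organs, gas, noise, then beacon artifacts.

    Truth masks are analytic (independent of the noise realization) and must
    be pairwise disjoint; the suggested seed for each organ is the rounded
    centroid of its mask.
    """
    masks: Dict[str, np.ndarray] = {}
    for organ in spec.organs:
        masks[organ.name] = ellipse_mask(
            spec.shape, organ.center, organ.axes, organ.rotation
        )
    names = list(masks)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if np.logical_and(masks[a], masks[b]).any():
                raise ValidationError(f"organs {a!r} and {b!r} overlap")

    rng = np.random.default_rng(spec.rng_seed)
    image = np.full(spec.shape, spec.background_intensity, dtype=float)
    for organ in spec.organs:
        m = masks[organ.name]
        image[m] = organ.mean_intensity
        if organ.texture_sigma > 0:
            image[m] += rng.normal(0.0, organ.texture_sigma, int(m.sum()))

    if spec.gas_fraction > 0:
        rectum = next((o for o in spec.organs if o.name == "rectum"), None)
        if rectum is None:
            raise ValidationError("gas_fraction > 0 requires a rectum organ")
        scale = math.sqrt(spec.gas_fraction)
        gas = ellipse_mask(
            spec.shape,
            rectum.center,
            (rectum.axes[0] * scale, rectum.axes[1] * scale),
            rectum.rotation,
        )
        image[gas] = spec.gas_intensity

    if spec.noise_sigma > 0:
        image += rng.normal(0.0, spec.noise_sigma, spec.shape)

    if spec.beacons:
        image = add_beacon_artifacts(image, spec.beacons, rng)

    seeds = {}
    for name, m in masks.items():
        rows, cols = np.nonzero(m)
        seed = SeedPoint(int(round(rows.mean())), int(round(cols.mean())))
        if not m[seed.row, seed.col]:  # centroid of a convex ellipse is inside
            raise ValidationError(f"centroid seed for {name!r} fell outside its mask")
        seeds[name] = seed
    return PhantomCase(
        image=image,
        truth_masks={k: v.astype(np.uint8) for k, v in masks.items()},
        suggested_seeds=seeds,
        spec=spec,
    )


def _pelvis_organs(
    prostate_intensity: float = 120.0,
) -> Tuple[OrganSpec, OrganSpec, OrganSpec]:
    """Shared anterior-to-posterior geometry: bladder, prostate, rectum."""
    return (
        OrganSpec("bladder", center=(56.0, 96.0), axes=(26.0, 32.0), mean_intensity=150.0),
        OrganSpec("prostate", center=(108.0, 96.0), axes=(20.0, 24.0), mean_intensity=prostate_intensity),
        OrganSpec("rectum", center=(152.0, 96.0), axes=(16.0, 22.0), mean_intensity=125.0),
    )


def _prostate_beacons() -> Tuple[BeaconSpec, BeaconSpec, BeaconSpec]:
    # three implanted transponders, offset from the centroid so the suggested
    # seed window stays on clean tissue
    return (
        BeaconSpec(center=(100, 88)),
        BeaconSpec(center=(106, 105)),
        BeaconSpec(center=(116, 92)),
    )


def default_scenarios(rng_seed: int = 0) -> Dict[str, PhantomSpec]:
    """The shipped study conditions, from easy to hard.

    * ``baseline``       — high contrast, no artifacts (all organ CNR >= 5);
    * ``beacons``        — three transponders implanted in the prostate;
    * ``low_contrast``   — prostate barely above background (CNR <= 2);
    * ``gas``            — a gas pocket occupying 35% of the rectum area.
    """
    base = PhantomSpec(organs=_pelvis_organs(), rng_seed=rng_seed)
    return {
        "baseline": base,
        "beacons": replace(base, beacons=_prostate_beacons()),
        "low_contrast": replace(base, organs=_pelvis_organs(prostate_intensity=90.0)),
        "gas": replace(base, gas_fraction=0.35),
    }
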