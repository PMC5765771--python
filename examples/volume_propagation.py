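"""Segment a slice stack by propagating the seed through mask centroids.

Builds a 5-slice stack of shrinking noisy ellipses (a crude organ tapering
out of plane), seeds only the first slice, and lets the pipeline carry the
seed forward via each mask's centroid.  Prints per-slice mask areas and
Dice scores against the per-slice ground truth.
"""

from mwdhseg import (
    OrganSpec,
    PhantomSpec,
    SeedPoint,
    evaluate_masks,
    generate_phantom,
    segment_volume,
)

slices, truths = [], []
for i in range(5):
    shrink = 1.0 - 0.12 * i
    case = generate_phantom(
        PhantomSpec(
            shape=(96, 96),
            background_intensity=80.0,
            noise_sigma=5.0,
            organs=(
                OrganSpec(
                    "prostate",
                    center=(48.0, 48.0),
                    axes=(24.0 * shrink, 30.0 * shrink),
                    mean_intensity=140.0,
                ),
            ),
            rng_seed=100 + i,
        )
    )
    slices.append(case.image)
    truths.append(case.truth_masks["prostate"])

masks = segment_volume(slices, SeedPoint(48, 48), seed_slice=0)
for i, (mask, truth) in enumerate(zip(masks, truths)):
    rep = evaluate_masks(mask, truth)
    print(f"slice {i}: area={int(mask.sum()):5d}  DSC={rep.dsc:.3f}")
print("\nOnly slice 0 was seeded by hand; the rest inherited the previous")
print("mask's centroid. DSC stays high as the organ shrinks.")
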