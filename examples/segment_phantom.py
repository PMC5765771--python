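"""Segment all three organs of the baseline pelvic phantom from one seed each.

Generates the high-contrast phantom slice, runs the seeded wavelet-domain
pipeline at each organ's suggested seed (its centroid), and prints the
overlap metrics against the analytic ground truth.  DSC near 1 means the
recovered mask almost coincides with the true ellipse; ΔV is the percent
volume error of the segmentation.
"""

from mwdhseg import (
    batch_evaluate,
    default_scenarios,
    generate_phantom,
    segment_slice,
)

case = generate_phantom(default_scenarios(rng_seed=0)["baseline"])

cases = []
for organ, seed in case.suggested_seeds.items():
    result = segment_slice(case.image, seed)
    print(
        f"{organ:9s} seed=({seed.row},{seed.col})  "
        f"T_L={result.thresholds.t_low:7.2f}  T_H={result.thresholds.t_high:5.2f}  "
        f"mask area={int(result.mask.sum())}"
    )
    cases.append((result.mask, case.truth_masks[organ], organ))

print()
table = batch_evaluate(cases)
print(table[["label", "dsc", "sensitivity", "inclusiveness", "delta_v_percent"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\nT_L is the adaptive low-band threshold (intensity units); T_H the")
print("high-band coefficient threshold (3x the estimated noise level).")
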