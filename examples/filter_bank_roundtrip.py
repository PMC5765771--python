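"""Decompose an image into the nine sub-bands and reconstruct it exactly.

Builds a noisy test image, runs the three-channel double-Haar analysis,
prints the energy in each sub-band and the round-trip error.  The (0,0)
band holds the smoothed image (almost all the energy); the eight
high-frequency bands hold edges and noise; the reconstruction error is at
machine precision because the bank is perfect-reconstruction.
"""

import numpy as np

from mwdhseg import analyze_2d, double_haar_bank, synthesize_2d

rng = np.random.default_rng(0)
image = np.full((64, 64), 100.0)
image[20:44, 20:44] = 160.0  # a bright square
image += rng.normal(0, 5, image.shape)

bank = double_haar_bank()
bands = analyze_2d(image, bank)

print("energy fraction per band (row channel, column channel):")
total = sum(float((b**2).sum()) for b in bands.bands.values())
for r in range(3):
    row = "  ".join(
        f"({r},{c}) {float((bands[(r, c)]**2).sum()) / total:8.2e}" for c in range(3)
    )
    print("  " + row)

back = synthesize_2d(bands, bank)
print(f"\nround-trip max abs error: {np.abs(back - image).max():.2e}")
print("(0,0) carries the image identity; channels 1/2 carry first/second-")
print("difference detail; an error at machine precision confirms perfect")
print("reconstruction.")
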