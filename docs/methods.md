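# Methods

## The transform

The segmentation operates in the domain of a three-channel double-Haar
filter bank. Both analysis high-pass filters have zero-sum taps, so
constant regions map to exactly zero in every high band; the low-pass taps
sum to one, so the (0,0) band is a local average on the intensity scale of
the image. The bank is the two-stage Haar cascade — analysis
`h0 = [1,2,1]/4`, `h1 = [1,0,−1]/2`, `h2 = [1,−2,1]/4`, synthesis
`g0 = [1,2,1]/4`, `g1 = [−1,0,1]/4`, `g2 = [1,−2,1]/4` — chosen because it
is the shortest double-Haar realization (3 taps, hence an exact 3×3
moving window in 2D) and because `Σ gᵢhᵢ = z⁻²` is a pure delay, giving
perfect reconstruction. The transform is undecimated: every band keeps the
image size, which keeps thresholding decisions pixel-aligned and avoids
the shift-variance of critically sampled transforms. A single
decomposition level is used; the structures of interest are large relative
to the 3×3 window, and deeper levels would only smooth the boundary
localization the high bands exist to provide.

Boundaries use half-sample symmetric extension (edge sample repeated).
This choice is load-bearing twice over: it makes the low band preserve the
image mean exactly (whole-point mirroring does not), and — with synthesis
extending each channel by the parity of its analysis filter, even for the
symmetric `h0`/`h2` channels and odd for the antisymmetric `h1` channel —
the analysis/synthesis round trip is an exact identity including the
border pixels, not merely in the interior. Delay is compensated by
center-aligning all correlations. All arithmetic is double precision.

## Adaptive thresholding

The user provides one seed pixel inside the structure. Statistics are
collected on the **low band** in a `(2r+1)²` window (default `r = 1`,
matching the transform's own window), clipped at the image border, with
population (divide-by-N) variance throughout.

`T_L` comes from two-class iterative-mean clustering: class A is
initialized at the seed-window mean, class B at the mean of the pixels
lying farther from the seed mean than the global mean does (falling back
to the single farthest pixel if that set is empty); pixels are reassigned
to the nearest class mean until both means move less than 1e-6 (at most
100 sweeps, ties to the seed class), and `T_L` is the midpoint of the
converged means. The construction uses only distances and means, so it is
equivariant under increasing affine intensity maps — the basis of the
pipeline's shift invariance. A constant band raises a degenerate-input
error: no two classes exist.

The **high bands** are denoised with a Lee filter — per pixel, with local
window mean `m` and variance `v`, gain `k = max(0, v − σ²)/v` (`k = 0`
where `v = 0`) and output `m + k(w − m)` — and then hard-thresholded at
`T_H = c·σ̂` with `c = 3` by default (the conventional detection
threshold; exposed as a config knob). The noise scale `σ̂` is the median
absolute coefficient of the finest diagonal band divided by 0.6745, the
standard robust estimator for Gaussian noise; one global `T_H` is applied
to all eight bands, since their noise derives from the same image noise.
Filtering precedes thresholding so that the threshold acts on denoised
coefficients. With `σ = 0` the filter short-circuits to the exact
identity rather than computing `m + 1·(w − m)`, which would differ by
round-off.

## From coefficients to a mask

The low band is replaced by a two-level image: the seed-class mean on the
seed's class, the complement-class mean elsewhere. After synthesis the
reconstruction is cut at `bg + binarize_level·(obj − bg)` (default
midpoint, ties to foreground). Anchoring both levels and the cut to the
two class means — rather than to a fixed zero floor — has two effects:
adding a constant to the image moves every quantity by that constant and
leaves the mask bit-identical, and structures darker than their
surroundings (the gas pocket, rectum on some protocols) are handled by the
same rule with no special case. The retained high-band coefficients
sharpen the cut at true edges; on a noiseless two-level image the
recovered mask is exactly the true region.

Post-processing keeps the 4-connected component containing the seed and
fills holes whose background is 8-connected (so diagonal leaks do not
count as enclosure). If the seed pixel itself is unlabeled the pipeline
raises an empty-result error — segmentation failed, and callers should
treat it as such rather than receive an empty mask silently.

Stacks are segmented slice-by-slice from a seed slice outward; each
neighbour inherits the rounded centroid of the previous mask as its seed.
A direction terminates when a slice fails (empty result, degenerate slice)
or when the propagated mask balloons past 8× its neighbour's area, which
in practice means the centroid landed on background and the cluster
grabbed the background class; terminated slices report empty masks.

## Evaluation

Dice, sensitivity, inclusiveness and ΔV are computed from voxel counts;
physical volumes are available when spacing is known. ΔV is signed as
defined, with a magnitude option for conventions that print only positive
values. An empty ground truth is an error (every ratio is undefined); an
empty segmentation yields DSC = sensitivity = 0, ΔV = −100%, and
inclusiveness reported as 0 with an explicit `inclusiveness_defined=False`
flag rather than a NaN that would poison downstream tables.

## The phantom

The generator emulates the imaging conditions the method targets, not CT
physics: three non-overlapping elliptical organs at distinct mean
intensities on a uniform background, i.i.d. Gaussian pixel noise, beacons
as small discs set to a high peak intensity with radial alternating-sign
streaks under an exponential envelope `A·exp(−d·λ)`, and an optional gas
pocket as a concentric interior ellipse of the rectum at near-minimum
intensity. Ground truth is the analytic ellipse membership, independent of
the noise realization; suggested seeds are mask centroids. Everything is
deterministic given `rng_seed`.

Default conditions (192×192, background 80, bladder 150 / prostate 120 /
rectum 125, noise σ = 6) put every organ at contrast-to-noise ≥ 5 in the
baseline scenario; the low-contrast scenario drops the prostate to 90
(CNR ≤ 2) and the gas scenario replaces 35% of the rectum area. The
beacon scenario implants three transponders (radius 2, peak 400, 8 streaks
of amplitude 25, decay 0.06/px) inside the prostate, mirroring the
three-transponder implant pattern. These constants were chosen once to
bracket an easy regime and the two documented hard regimes; they are not
fits to any patient data.

What passing on the phantom shows — and what it does not: the pipeline
recovers piecewise-constant-plus-noise structures at realistic CNR through
beacon-type artifacts, degrades the way the method is known to degrade
(over-segmentation at low contrast, gas capture), and is exactly
reproducible. Real CBCT adds untextured-model violations the phantom does
not emulate: intensity inhomogeneity, organ texture, partial-volume
boundaries, correlated reconstruction noise, and true beam-hardening
streaks. Phantom scores therefore validate the mechanism, not clinical
accuracy.

## Numerical and interface choices

* Seed coordinates are 0-based `(row, col)` pixel indices everywhere.
* A seed's low-band value exactly at `T_L` counts as "above";
  reconstruction values exactly at the binarization cut are foreground.
* The window-statistics kernels accumulate window elements in row-major
  sequential order so a per-pixel hand evaluation reproduces them bitwise.
* Masks are 0/255 in PNG (viewer-friendly) and 0/1 in NIfTI; manifests
  record thresholds, seed, config and a config hash so identical runs are
  byte-identical.
* Problem sizes in the shipped scenarios and the acceptance script
  (192×192 slices, 100 random 64×64 round-trip images) are desk-scale
  choices that exercise every code path while keeping a full run under a
  minute.

## Known limitations

Single seed per structure (multiple seeds would help the two failure
modes); 2D slice-wise processing with centroid propagation rather than a
3D transform; one decomposition level; no surface-distance metrics; the
phantom's organs are uniform ellipses. The threshold clustering is
two-class: when more than two tissue classes are present it merges the
classes nearest the seed's side, which is why the connected-component step
is part of the method and not cosmetic.
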