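# Methods

This document records the algorithmic choices behind each stage of the
`seedshape` workflow, with the rationale for the non-obvious ones.

## Geometric models

Lateral models (`LM*`) are built from the cardioid `r(θ) = a(1 + cos θ)`,
drawn point-down (the notch, corresponding to the hilum region, faces the
micropylar end). Modifiers, applied in polar form:

- **flatten / elongate** — anisotropic scaling of the x or y extent;
- **notch opening** `ν` — blends the cardioid toward a circle,
  `r = a[(1 − ν)(1 + cos θ) + ν]`, shallowing the notch;
- **hilum bump** — a `cos²` protrusion in a 0.9-rad window around the notch.

Dorsal models (`DM*`) are super-ellipses `|x/a|ⁿ + |y/b|ⁿ = 1`, whose area
`4ab·Γ(1 + 1/n)² / Γ(1 + 2/n)` is used as an analytic oracle in the tests.
All models are represented as unit-area boundary polygons with the centroid
at the origin, so a single scale parameter maps them to pixels. Preset
parameters live in `presets.yaml`; arbitrary model rasters can be loaded
with `load_model_image`.

## Segmentation and morphometry

Plates are thresholded with Otsu's method (with a configurable polarity),
labeled, and filtered: components touching the border or below `min_area_px`
are rejected and counted in the segmentation report. Labels are assigned
row-major so they match the physical plate layout.

Measured traits: area `A`, perimeter `P`, length `L` (horizontal extent in
the canonical pose), width `W`, aspect ratio `AR = L/W`, circularity
`C = 4πA/P²`, roundness `R = 4A/(πL²)`. The perimeter uses the
`skimage.measure` perimeter estimator (Crofton-style), which converges to
the true contour length for smooth shapes; on a digital square it is biased
upward in the usual way, which is why the square's circularity oracle in the
tests is ≈ π/4 rather than the continuous value.

## Orientation

Every silhouette is rotated into a canonical pose before averaging or
fitting, because J-index registration is translation + scale only (see
below). The procedure:

1. Extract the smoothed boundary and resample the radial profile `R(θ)`
   about the centroid on a uniform 720-point grid.
2. Score every reflection of the profile (each reflection index fixes a
   distinct axis over a half-turn); the deepest local minima of the mismatch
   score are candidate mirror axes, plus the perpendicular of the best one.
3. Rotate the mask to put each candidate axis horizontal, then choose:
   - **lateral view** (one mirror axis): the candidate with the largest
     excess of horizontal-mirror overlap over vertical-mirror overlap;
   - **dorsal view** (two mirror axes): the wider-than-tall candidate.
4. Flip left–right if the mean boundary radius in a ±40° window facing
   right exceeds the left window (the notch — smaller radius — faces right).

The view is taken from the run configuration rather than inferred, because
at realistic boundary-noise levels (≈ 3%) weakly-notched lateral shapes and
noisy dorsal ellipses genuinely overlap in every symmetry statistic we
evaluated; the photographic view is always known in practice. When the view
is not supplied, a heuristic (mirror-overlap excess ≥ 0.015) decides, and is
correct on all built-in presets.

A principal-axis (second-moment) orientation was evaluated and rejected: the
cardioid is taller than wide, so the major principal axis is *perpendicular*
to its symmetry axis and canonical fits collapse.

## Silhouette averaging

The population average is a per-pixel occupancy map: silhouettes are
centroid-aligned (optionally rescaled to the mean equivalent-circle radius
so size spread does not erode the boundary) and stacked; a pixel belongs to
the average when at least a fraction `tau` of seeds cover it. This is the
exact mathematical formalization of overlaying equally-transparent layers
and keeping the darkest region. `tau = 1` gives the intersection, `tau → 0`
the union; the default `tau = 0.8` keeps the region where a large majority
of seeds coincide, which is robust to single outliers while still excluding
noise-driven protrusions.

## J-index registration

`J = 100 · |seed ∩ model| / |seed ∪ model|` (a percent Jaccard index).
Fitting maximizes J over a similarity transform. Degrees of freedom:
**translation + isotropic scale by default**, because rotation is already
resolved by the canonical orientation step and adding it makes the
objective multimodal for symmetric models; optional rotation, mirror flip
and anisotropic scale are available via `FitConfig`. The optimizer uses an
analytic start (`s₀ = √area`, centroid-matched translation), a three-level
coarse-to-fine grid, and a Nelder–Mead refinement on `(log s, ty, tx)`; the
fit can never score below the analytic start. `standardize_height` rescales
the silhouette to a fixed working height before fitting (default 400 px) so
runtime is independent of image resolution; the returned placement is in
native pixels.

## Statistics

Groups are compared with the Kruskal–Wallis rank test (chi-square
approximation). Homogeneous groups are found with a stepdown procedure on
the rank ordering: subsets of `p` groups that are contiguous in mean-rank
order are tested at nominal level `α_p = 1 − (1 − α)^{p/k}` for
`p ≤ k − 2` and `α` for `p ∈ {k−1, k}`; a subset is declared homogeneous if
it is non-significant and reachable (not contained in an already-rejected
chain). Maximal homogeneous subsets are converted to compact letter
displays. Tests validate the letters against a brute-force closed-testing
oracle for up to four groups and verify by simulation that the familywise
error under the full null stays at ≈ α. Summary tables report
`mean ^letters^ (CV%)` per trait and group.

## Synthetic generator

Seeds are drawn from a base model with two independent perturbations:

- **size** — a lognormal factor parameterized by the linear CV
  (`σ² = ln(1 + cv²)`, mean 1);
- **shape noise** — a random radial-harmonic field
  `r(θ) · (1 + Σₖ aₖ cos kθ + bₖ sin kθ)`, harmonics `k = 2..8`, with the
  amplitude parameter equal to the RMS of the field. Draws that would
  collapse the radius (factor ≤ 0.05) are rejected as unrealistic.

Ground truth (planted scale, size factor, position) is returned alongside
the masks, enabling closure tests: segmentation recovers the planted areas,
measured size CVs match the planted CVs, and fitted J degrades
monotonically with noise.

**Known limit:** the harmonic noise is smooth and band-limited, so it barely
roughens the perimeter. One consequence, confirmed empirically: circularity
`C = 4πA/P²` is nearly as stable as the J index under this generator
(CVs ≈ 0.9% both), whereas real seed coats have high-frequency texture that
inflates `P` and makes `C` noisier than `J`. The validation therefore
asserts that `CV(J)` is below `CV(AR)`, `CV(R)` and the mean shape-trait
CV, rather than below every shape trait individually.
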