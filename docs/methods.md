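# Methods

This note documents the models, numerical choices and limitations behind
`fretstack`, and what the synthetic test conditions do and do not
demonstrate about real microscopy data.

## Background model and tile classification

The observed frame is modelled as I(x, y) = b(x, y) + S(x, y) + ε, with a
smooth additive shading field b, sparse object signal S, and sensor noise
ε ~ N(0, σ²). The estimator assumes most tiles contain *only* b + ε, which
holds for frames with one or few objects of interest; it is explicitly not
designed for frames densely and homogeneously covered by cells — there the
background cluster starves (< 6 tiles) and the frame is flagged rather
than corrected.

Tiles are squares of ⌊width/window⌋ pixels; `window` is the number of
tiles across the image width (default 40, i.e. 16 px tiles on a 640-wide
frame). Remainder strips at the right/bottom edge when the frame is not an
exact multiple stay untiled but are covered by surface extrapolation.
Six features summarize a tile: median, population standard deviation,
skewness, excess kurtosis, and the intensity-weighted centroid in
tile-local coordinates. Centroids are tile-local deliberately: background
tiles then cluster together regardless of where they sit in the shading
gradient, whereas frame-global centroids would make position itself a
clustering feature. Degenerate tiles use fixed conventions — zero-variance
tiles have skewness = kurtosis = 0 and all-zero tiles put the centroid at
the tile center — so that NaN never reaches the clustering step. The
moments are computed directly from their definitions rather than through a
statistics library because those conventions (and warning-free behavior on
constant tiles) are part of the contract.

Features are standardized per frame to zero median and unit interquartile
range before clustering, making one Euclidean ϵ meaningful across the six
mixed-unit dimensions, across frames and across channels. DBSCAN
(scikit-learn, Euclidean metric, `min_samples` default 5) groups the
tiles; ϵ is the user-tuned maximum feature-space distance between tiles in
one cluster, settable per frame range. The background is the cluster whose
members have the lowest mean raw median intensity — the dimmest dense
population — with noise tiles always treated as foreground. On the
synthetic study conditions the standardized background cloud has
nearest-neighbour spacing ≈ 0.6–0.9 while foreground tiles sit ≥ 99 units
away, so any ϵ in roughly 1–30 behaves identically; the package default
is 1.5. Real data with dimmer objects will need ϵ tuned per dataset, which
is the intended workflow.

Note that the number of DBSCAN clusters is not monotone in ϵ (growing ϵ
can both merge clusters and promote former noise into new clusters); what
is monotone, and what the property suite asserts, is the set of
non-noise points.

## Background surface

"Quadratic interpolation" of the background-tile medians is realized as a
degree-2 tensor-product least-squares spline (`LSQBivariateSpline`,
kx = ky = 2) over the scattered tile centers, with no interior knots by
default — a single biquadratic patch whose span contains every quadratic
polynomial surface. Two numerical details matter:

- The spline's bounding box is set to the full frame, not the data hull;
  fitpack otherwise clamps evaluation at the outermost tile centers and
  the ~8 px frame margin (plus any untiled remainder strip) would get a
  constant extension instead of the polynomial one.
- An interpolating scattered-data spline (smoothing 0) was rejected: on a
  regular grid with a hole where the foreground was removed, the fitpack
  solver is rank-deficient and produced errors of ~180 counts on an exact
  quadratic test surface. The least-squares patch reproduces the same
  surface to 1e-12 and is insensitive to holes.

With fewer than 9 background tiles (the biquadratic patch's coefficient
count) a global 6-coefficient quadratic polynomial is fitted instead;
below 6 tiles the frame fails. Subtraction is rounded and clipped to
[0, 2^bit_depth − 1]. About half of the true-background pixels stay
positive after subtraction (the positive half of the noise), so the
corrected background has mean ≈ σ/√(2π) ≈ 0.4 σ and reduced spread —
which is what the residual bounds in the acceptance suite check.

## Registration

The dual-view offset is modelled as a static rigid transform (dx, dy, θ
about the image center); it is estimated once on the first frame and
applied to all frames (per-frame re-estimation is a config flag).
Estimation: sub-pixel cross-correlation (no phase whitening — whitening is
noise-dominated on smooth fluorescence frames and can lock onto spurious
peaks) initializes the shift, then Powell refines (dx, dy, θ) within
±10 px / ±10° by maximizing normalized cross-correlation. Two details
protect the criterion from known biases:

- NCC is computed on *self-quotient* renderings (image divided by a
  σ = 20 px smoothed copy, denominator clamped at 5 % of its maximum).
  This cancels smooth multiplicative structure — shading, and any real
  spatial ratio gradient between the channels — which otherwise biases an
  intensity criterion by up to ~2 px along the object axis. The clamp
  keeps the quotient bounded on background-subtracted frames whose
  background is near zero.
- A border margin (2.25 × the quotient smoothing scale) is excluded, so
  the zero-filled strip that any prior warp leaves at the frame edge
  cannot attract the optimum.

Warping uses inverse mapping with bilinear sampling and zero fill.
Optimization failure returns the identity with a `registration_warn`
metric flag rather than an exception.

## Ratio stage

Order of operations: register, bilateral-smooth, threshold, clean, divide.
The bilateral filter is the textbook product of a spatial Gaussian
(radius ⌈3 σ_space⌉, reflect padding) and an intensity-difference
Gaussian, normalized per pixel; defaults σ_space = 2 px and
σ_range = 5 % of the bit-depth range. It is implemented in-package with
these exact semantics so a per-pixel direct-summation oracle can verify
it; library bilateral filters use different windowing/normalization
conventions that make such verification impossible.

Otsu's threshold (scikit-image) is computed per frame and channel; the
threshold convention is lower-class-boundary inclusive, and the test
oracle therefore compares induced partitions, not threshold floats.
Border "singularities" are 8-connected components that touch the frame
border and are smaller than 1 % of the frame area (configurable); the
largest component is always kept, so a principal object touching the
border survives. The ratio is acceptor/donor on the intersection of the
two channel masks; masked pixels with donor = 0 are set to 0 and counted.
Display rescaling maps the foreground's [P10, P90] to [0, 255] with
clipping; a flat frame renders mid-gray and is flagged.

## Photobleaching

The trace fitted is the *median foreground intensity* per frame — the
median over pixels above the frame's Otsu threshold. A plain or non-zero
median of a background-subtracted frame is dominated by clipped background
noise whenever the object is sparse, and would hide the decay entirely.
Models: M(t) = a + b·t or M(t) = A·e^(−kt), the latter fitted as a linear
regression on ln M (deterministic and adequate for monotone decays;
heavy heteroscedasticity would argue for a nonlinear fit, which is not
provided). "Regularized" means an optional ridge penalty on the slope/rate
term only, default λ = 0 so the plain least-squares fit is the default
behavior. Correction factors are c(t) = M(onset)/M(t) from the onset
(the fit range's lower bound) onward and exactly 1 before; the fit rejects
trends that become non-positive anywhere they would be applied. Frames
flagged as failed by background subtraction are excluded from the trace.
Ratio-stack correction multiplies by c_acceptor/c_donor, which is exactly
1.0 when both channels share a model — common bleaching cancels in a
ratio, and the implementation preserves that bit-exactly.

## Synthetic study conditions

The generator renders, per channel: a quadratic background
b(x, y) = a0 + a1x + a2y + a3x² + a4xy + a5y² (defaults span ≈ 200 counts
peak-to-peak over 640×480), a capsule-shaped object with Gaussian
cross-section (half-width 18 px, peak 2000 counts, tip advancing 2
px/frame), i.i.d. Gaussian read noise (σ = 5), per-channel exponential
object decay (donor k = 0.03/frame), and a tip-focused acceptor/donor
ratio field 1 + 0.5·exp(−d_tip²/(2·60²)) emulating a tip-localized
analyte gradient. The acceptor frame is warped by the inverse of a
(3, −2, 1°) rigid offset before noise, so that offset is exactly what
registration should recover. One seeded generator drives all draws;
identical spec + seed gives bit-identical stacks. Poisson shot noise is
available but off by default, keeping the residual-noise bounds analytic.

What passing on these conditions does *not* show: robustness to shading
that is not quadratic (the default surface has no interior knots and
will low-pass such structure), to dense cell fields, to strong shot noise
or camera artifacts, to non-rigid channel distortion, or to bleed-through
between spectral channels (explicitly out of scope — the tool assumes
linked constructs with fixed stoichiometry).

Problem sizes used by the test and reproduction suites: the full study
conditions (640×480, 20 frames) for background, registration and
end-to-end recovery; a 240×320, 6-frame variant of the same physics for
pipeline determinism and orchestration checks; 50-frame traces for the
bleach fits; ≤ 30-point instances for the exhaustive DBSCAN comparison.

## Known limitations

- Background designation can in principle mis-pick a small dim foreground
  cluster if it is both denser than `min_samples` and dimmer on average
  than the true background; raising `min_samples` or tightening ϵ per
  range is the remedy, guided by the `n_background_tiles` metric.
- Exponential bleach fitting on log-medians weights early (bright) frames
  less than a nonlinear fit would; with 2 % multiplicative noise the rate
  error stays well under 10 %, but very noisy tails may need a restricted
  fit range.
- The discontinuity detector flags |Δ metric − median Δ| > z·MAD·1.4826
  (default z = 5); it is a screening aid, and flagged frames still need
  visual confirmation before reprocessing.
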