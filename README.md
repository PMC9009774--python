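# fretstack

Processing of ratiometric FRET time-lapse image stacks: cluster-based
background subtraction, registered acceptor/donor ratio-image construction
with per-frame quality metrics, and photobleaching correction — as a
library and a configuration-file-driven command line tool.

## The problem

Ratiometric FRET biosensors (linked donor–acceptor fluorescent constructs
with fixed pixelwise stoichiometry) report an analyte concentration through
the acceptor/donor emission ratio R(x, y) = I_A(x, y) / I_D(x, y). Before
that ratio means anything, each channel must be cleaned of two biases:

- **Shading background** — a smooth additive field b(x, y) from uneven
  illumination and detector offset that varies across the frame and over
  long time-lapses;
- **Photobleaching** — a multiplicative decay of the fluorophore signal
  over time, M(t) ≈ A·e^(−kt), that masquerades as a drifting ratio when
  the two channels bleach at different rates.

`fretstack` targets the common regime of one (or few) bright elongated
cells — e.g. a growing pollen tube imaged in a dual-view setup — where
most of the frame is background and the background can therefore be
estimated retrospectively from the image itself.

## The method

**Background subtraction.** Each frame is tiled into squares (`window`
tiles across the image width; a 640×480 frame at `window = 40` gives 1200
tiles of 16×16 px). Every tile is summarized by six features: the median,
standard deviation, skewness and excess kurtosis of its intensity
distribution, plus the tile-local intensity-weighted centroid (x, y).
After robust per-frame standardization (median/IQR), DBSCAN with a
Euclidean metric and user-supplied radius ϵ clusters the tiles; the
cluster with the lowest mean raw median intensity is the background, and
everything else (other clusters and noise tiles) is foreground. The
background tiles' medians are interpolated by a degree-2 surface over the
full frame and subtracted (clipping at 0 and the bit-depth maximum). ϵ can
be set per frame range, so outlier frames can be reprocessed individually;
frames where clustering or the surface fit fails are passed through
unchanged and flagged.

**Ratio construction.** The acceptor stack is registered onto the donor by
a rigid transform (dx, dy, θ) estimated by sub-pixel phase correlation
plus local optimization of a normalized cross-correlation criterion; both
channels are then denoised with a small-kernel bilateral filter, binarized
with per-frame Otsu thresholds, cleaned of small border-touching
components, and divided on the joint mask. For display, the ratio's
10th–90th percentile span (computed over foreground pixels only) is mapped
linearly to 8 bits, so single outliers cannot compress the visible
dynamics.

**Photobleaching correction.** A regularized linear or exponential trend
is fitted to the median foreground intensity trace over a configured frame
range; every frame from the onset (the range's lower bound) is rescaled by
c(t) = M(onset)/M(t). Correcting both channels by the same trend leaves
the ratio bit-identical, as it should.

**QC metrics.** Per frame and channel: percentage of non-zero pixels,
median foreground intensity over the bit-depth maximum, cluster counts and
failure flags. Sharp frame-to-frame discontinuities in these series (a
robust MAD-based test) point to frames that need a different ϵ.

## Worked example

Generate a synthetic dual-channel stack with known ground truth (quadratic
shading spanning ~200 counts, Gaussian noise σ = 5, a bright capsule-shaped
cell with a tip-focused ratio gradient, a (3, −2) px + 1° dual-view offset
of the acceptor, donor bleaching at k = 0.03/frame), then run the full
pipeline on it:

```
fretstack synth -o fixture
fretstack run -c run.ini
```

with `run.ini`:

```ini
[input]
donor = fixture/donor.tif
acceptor = fixture/acceptor.tif
output_dir = out

[run]
modules = background, ratio, bleach

[background]
window = 40
eps = 1.5

[bleach]
bleach_model = exponential
bleach_channels = donor
```

The run writes `corrected_donor.tif`, `corrected_acceptor.tif`,
`ratio_display.tif` (8-bit, robustly rescaled), `run.h5` (float ratio
stack, metrics, bleach factors), `metrics.csv`, `run.log` and
`manifest.json`. On this fixture the pipeline log reports the estimated
registration

```
registration dx=3.027 dy=-1.999 theta=0.9989 deg converged=True
```

against the constructed (3, −2, 1°) offset, and the fitted donor bleach
model `exponential params=(1582.69, 0.0298644)` against the constructed
rate 0.03/frame. The corrected background region is flat to within the sensor
noise and the masked ratio reproduces the constructed tip gradient to a
fraction of a percent (see the reproduction script below for the exact
measured numbers).

Frame indices in configuration files are 1-based and inclusive; e.g.
`ranges = 1-50:0.6, 51-100:0.9` applies ϵ = 0.6 to the first fifty frames.

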