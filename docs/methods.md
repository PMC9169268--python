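# Methods

## Forward model (simulator)

The simulator emulates a bench radiography setup: a 14-bit detector
(2304 × 1300 px, 49.5 µm pixels at full scale), a four-slot pod holder cut from
extruded polystyrene (eps), and a monochromatic parallel-beam approximation
(the real holder sits directly on the detector, so magnification ≈ 1 and rays
are effectively parallel per pixel).

Each pod phantom is a union of one or two ellipsoidal **shell lobes** (an outer
ellipsoid minus a concentric-axis cavity) enclosing one to three solid
ellipsoidal **kernels**. Ellipsoids were chosen because the chord length of a
z-directed ray through an ellipsoid is closed-form
(`L = 2·az·√(1 − ru² − rv²)`), which makes the Beer–Lambert forward model
`I = i0 · exp(−∑ μ·L)` exactly testable, and because two tangent lobes
reproduce the waisted two-lobe silhouette of a peanut pod. Lobes are kept
disjoint (0.4 mm gap) so volumes — and therefore masses — add exactly:
the stored ground-truth weights are `density × analytic volume` by
construction, not independent labels.

Trait sampling reproduces the gravimetric dataset the study design describes:
kernel weight in [0.003, 2.47] g and shell weight in [0.05, 1.40] g, drawn from
range-scaled Beta distributions — Beta(1.7, 3.4) and Beta(1.5, 4.5) — whose
right skew matches the reported over-representation of light pods (sample
means ≈ 0.79 g and ≈ 0.39 g). Kernel geometry is scaled so the drawn weight is
hit exactly; the shell wall is scaled around the kernel cavity likewise.
Kernel and shell weights are drawn **independently**; real pods correlate the
two, so synthetic shelling percentages reach slightly higher extremes than a
real crop would. Draws whose geometry exceeds the holder slot are rejected and
resampled (the practical effect is a mild truncation of the joint extreme of
both traits).

Radiometry (defaults, per mm): kernels μ = 0.07, shell μ = 0.004, eps bars
τ = 1.9 per crossing. These were set so that (i) the darkest pixels (bars,
large kernels) stay at or above the ≈707-count floor of the 14-bit raw range,
(ii) virtual-biomass values stay in the 0–2 band, and (iii) the shell is only
slightly darker than the background — which is exactly the regime in which the
Otsu-minus-offset segmentation convention is meaningful (the shell falls into
the background; the kernels, an order of magnitude more attenuating, form
their own histogram mode). A consequence worth knowing: the faint shell is a
weak target for the CNN (below).

Noise: counts are `Poisson(gain·expected)/gain` plus Gaussian read noise
(σ = 5), with gain (`photon_scale` = 8) chosen so blank-image SD ≈ 0.5% of i0,
consistent with the narrow reported flat-field drift. The per-scan flat field
i0 is drawn uniformly from the reported stability interval
[4864.444, 5382.635]. The holder is "re-placed" for every scan by a ±2 px grid
jitter; the blanks use the nominal grid position. The jitter is what creates
the *residual* grid bands that the labeling step must find — with a perfectly
static grid, blank subtraction would cancel the bars and the label stage would
be vacuous.

## Image treatment

Per holder projection: crop to the four slot interiors; average ≥ 2 blanks and
subtract pixelwise, taking `√(x²)` (identically `|x|`); threshold the
difference image to label grid residuals (≥ convention at the boundary);
estimate i0 as the mean of a small pod-free border region (default 40 × 30 px,
8 × 8 px at desk scale), sliding it along the border away from labels and
low-count (pod) areas when needed; replace labeled pixels with i0; transform
with `v = max(0, ln(i0/I))`. Pixels ≤ 0 counts are clamped to 1 count before
the log (they only occur at the noise floor). Grid-filled pixels map to
exactly 0.

The label threshold is kept at the scanner-convention absolute value 5250 as
the library default, but the synthetic experiments use a threshold *relative*
to the blank level (0.75 × blank mean). With a per-scan flat field drifting
over a ±5% interval, no single absolute counts threshold can separate bar
residuals (≈0.85·i0 in the difference image) from the darkest pod pixels
(≤0.73·i0) across all scans; the relative form separates them by > 4σ for
every i0 in the interval. This is a deliberate design choice of the package,
recorded here because the absolute convention is what a fixed-exposure
production scanner would use.

## XRT pathway

Otsu's threshold is computed by exhaustive minimization of the within-class
variance `σ²_w(t) = w0(t)σ²0(t) + w1(t)σ²1(t)` over every distinct gray level
(ties → smallest t). Candidates put pixels `< t` in class 0; this makes the
threshold shift-equivariant under constant offsets. The segmentation domain is
the grid-filled **intensity** image (kernels darkest); the offset (default 50
counts) is subtracted from the Otsu threshold so shell pixels near the
threshold drop into the background, and the foreground is every pixel strictly
below the shifted threshold. An alternative domain — the virtual-biomass image
rescaled to 16 bits with inverted polarity — is available behind a flag.

The mask is refined by erosion with a 5 × 5 rasterized ellipse then dilation
with a 9 × 9 ellipse (SE pixels: centers with `(dr/a)² + (dc/a)² ≤ 1`,
`a = (size−1)/2`). Outside-the-image counts as background for erosion. The
asymmetric pair nets a ≈2 px mask growth, which recovers the soft projected
rim of an ellipsoidal kernel; on coarse desk-scale pixels this fixed margin is
relatively large, so silhouette-overlap checks are run at the full-scale pixel
size where kernels span hundreds of pixels.

Kernel and shell integrals (`∑ v·mask`, `∑ v·(1−mask)`) partition the pod
total exactly up to float summation order (asserted at 1e-9 relative).
Calibration is ordinary least squares of grams on integral, fitted on the
calibration split only; negative predictions are floored at 0.

Known XRT biases, faithfully retained rather than corrected: the kernel
integral includes the shell attenuation along kernel rays (absorbed by the
calibration slope to the extent shell and kernel masses co-vary), and the
shell integral accumulates the clipped positive noise of the large background
area, which is why shell R² trails kernel R².

## CNN pathway

Architecture and recipe as in the README; defaults are frozen in `CNNSpec`.
Two structural choices were genuinely open and resolved as follows: five
convolutional layers (the per-layer description is authoritative over a
round-number layer count), and two hidden dense layers (the dropout wording
implies at least two; a third is configurable). No pooling follows conv5; the
5 × 5 × 256 tensor is flattened directly. Input images are zero-padded to
square and resized; 227 px reproduces the classic AlexNet size table
(55→27→23→11→9→7→5).

The desk-scale variant (`desk_spec`) keeps the layer inventory — five convs
with identical kernels and strides, two pools, two dropout-FC layers, two
outputs — but cuts widths (24/64/96/96/64 filters, 100-unit FCs) and uses a
163 px input, the smallest extent the valid-padded stack admits. Training 288
images for 30 epochs takes ≈50 s single-threaded.

Sample weighting: per trait, targets are histogrammed into 20 equal-width bins
over the observed range; a pod's raw weight is 1/count of its bin, the
combined weight is the mean over the two traits, normalized to mean 1. The
loss is `mean_i(w_i · mean_j(pred_ij − y_ij)²)`, so unit weights give plain
MSE exactly. Weights are applied per sample (scalar), not per output.

Reproducibility: all randomness (init, shuffling, dropout) derives from the
spec seed; with single-threaded BLAS two runs are bit-identical.

Desk-scale behavior: kernel weight is learned reliably (test R² ≈ 0.97 at 30
epochs, slope < 1 — the regression-to-the-mean shrinkage typical of an
L2-trained network on a skewed target). Shell weight is *not* learned at this
scale: the shell contributes only ≈0.02–0.05 to pixel values against a kernel
signal of ≈1, and at the fixed 5·10⁻⁵ learning rate the 180 desk-scale steps
leave the shell output near the target mean. This is a limitation of the
desk-scale synthetic conditions (faint shell radiometry, short training), not
of the training code — the 10-image memorization check drives *both* outputs
below 0.02 g MAE when given enough steps.

## Evaluation

The split is a seeded uniform shuffle sliced to |test| = round(0.10·N), then
|validation| = round(0.20·|calibration|); both predictors see the identical
split. Reported statistics: Pearson r; R² reported as r² (the goodness of the
simple linear fit of prediction on truth — the 1 − SSE/SST variant around the
1:1 line is kept in `extras`); MSE and MAE of raw residuals; OLS slope and
intercept of prediction regressed on truth (that direction is the package's
recorded convention). PCA for predictor comparison runs on standardized
columns per trait.

## Numerical choices and degenerate inputs

- Otsu on a constant image raises; an offset pushing the threshold below the
  minimum yields an empty mask with a warning.
- A zero-width trait range is a point mass (deterministic phantoms for tests).
- Identical targets give uniform sample weights rather than an error.
- i0 ≤ 0 raises; pixels above i0 clip to v = 0.
- Counts are integer-quantized, so noiseless i0 recovery is exact only to
  ±0.5 counts.

## Problem sizes

The shipped experiments use a 160 × 256 detector at 0.4 mm pixels, 100
projections (400 pods) for the end-to-end studies, and the width-reduced CNN;
these sizes were chosen so the whole study runs in about a minute on a single
CPU while every stage still does nontrivial work. The full-scale geometry
(1300 × 2304 at 49.5 µm, the 227-px CNN) is exercised structurally (builds,
forward pass, segmentation oracle at full pixel density) but not trained.

## What passing tests do and do not show

The simulator shares its geometry primitives with no stage of the analysis
pipeline, and every algorithmic step is checked against an independent oracle
(quadratic-root chords, exhaustive Otsu, by-definition morphology sweeps,
textbook metric formulas). Passing therefore shows the pipeline implements its
stated mathematics and recovers known ground truth under the stated noise
model. It does not show performance on real scans: real pods have
inhomogeneous tissue, polychromatic beam-hardening, scatter, detector PSF,
correlated kernel/shell masses, and manual-labeling artefacts, none of which
are modeled.
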