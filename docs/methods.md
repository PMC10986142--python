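# Methods

## Overview

`glut4quant` quantifies the subcellular distribution of GLUT4 in confocal
cross-sections of single skeletal-muscle fibres. Each field carries three
co-registered channels: dystrophin (lining the inner face of the plasma
membrane), GLUT4, and MHC1 (slow myosin, marking type I fibres). The
pipeline answers, per fibre: how much GLUT4 is present in the membrane band
and in each of five concentric 1 µm layers beneath it; how many GLUT4
clusters ("spots") of each size class sit in each layer; how strongly GLUT4
colocalizes with the membrane stain; and — across a study of repeated
biopsies — how these quantities change over an insulin-infusion time course
and differ between training-status groups, infusion arms and fibre types.

Because validation images for this assay are not publicly deposited, every
stage is validated by parameter recovery on synthetic fibres with complete
ground truth.

## Membrane segmentation

The membrane midline is found with a classical active contour (snake). The
dystrophin channel is Otsu-thresholded and the largest connected bright
component — the membrane ring — is hole-filled; its outer boundary seeds a
closed snake of 200 vertices. The snake minimises internal tension
(`alpha = 0.02`) and rigidity (`beta = 0.5`) energies plus an external
energy equal to the negative Gaussian-smoothed intensity (`sigma = 2` px),
so it settles on the ridge of the ring: the membrane midline. Updates use
the standard semi-implicit Euler scheme (step `gamma = 2`), with vertices
resampled to uniform arclength each iteration.

Convergence is declared when the mean vertex displacement per iteration
falls below 0.02 px (cap 500 iterations). This tolerance is deliberately
tighter than the displacement scale of the final glide onto the ridge: at a
0.1 px tolerance the snake halts while still sliding and leaves a ~0.4 px
systematic radial bias on a noiseless circle; at 0.02 px the residual bias
is below 0.01 px. Fibres touching the image border are rejected (the
contour cannot close), blank fields and sub-minimum enclosed areas raise a
segmentation failure, and non-convergence is reported as an error rather
than a silent partial result.

Measured on rendered phantoms at default noise, the contour RMS radial
error is ~0.06 px, far inside the 1 px acceptance envelope.

## Distance map and layers

The signed Euclidean distance from every pixel centre to the contour
polyline is computed exactly (vectorised point-to-segment geometry, not a
grid propagation), positive inside. Layer masks are cut from the distance
map `d` (in px, with `w` the 1 µm layer width in px):

- plasma-membrane band: `|d| <= 1.5` (3 px thick, centred on the midline);
- layer k (k = 1..5): `d` in `(1.5 + (k-1)w, 1.5 + kw]`;
- interior: `d > 1.5 + 5w`.

The bands are measured from the inner edge of the membrane band by
default; `layer_origin="midline"` measures them from the contour itself
(membrane-band pixels are never reassigned). Masks are pairwise disjoint
and their union is exactly `d >= -1.5`: the membrane band plus everything
inside. A fibre whose deepest layer would be empty raises an error; an
empty interior is legal (small fibres), and any unexpectedly empty layer
logs a warning.

At the default 0.2 µm/px a 1 µm layer is 5 px wide; the config warns below
2 px per layer.

## Spot detection and classification

A single intensity threshold per participant is computed by Otsu's
criterion on the pooled histogram of all of that participant's fibre-mask
pixels (integer levels; the first maximiser of the between-class variance
is taken on ties) and applied identically to all of their images. Pooling
across all of a participant's images, rather than per biopsy, makes the
three timepoints directly comparable within a participant.

Spots are 8-connected supra-threshold components within the membrane band
plus interior; components under 2 px are discarded as single-pixel noise.
Each component's size is its area-equivalent circle diameter
`2*sqrt(area/pi)`; a spot is **large** iff this strictly exceeds 1 µm and
**small** otherwise (exactly 1 µm is small). Layer assignment is by
centroid membership; components straddling layers are not split. A
component whose centroid pixel falls outside every band (possible for
concave shapes hugging the membrane) is assigned the layer of its member
pixel nearest the centroid.

Consequence of the centroid rule worth knowing: a large spot centred in
the 3 px membrane band necessarily pokes outside the analysed region; the
clipped component's centroid shifts inward and can land in layer 1. This
is inherent to the measurement definition, affects only the rare
large-at-membrane spots, and is visible in the recovery suite as a ~0.3%
layer mismatch.

Layer-wise fluorescence intensity is the arithmetic mean of the raw GLUT4
channel over each mask (no background subtraction or flat-fielding); an
empty mask yields a missing value, never zero. Colocalization is the
pixel-wise Pearson correlation between GLUT4 and dystrophin, by default
over the whole fibre including the membrane band (`pcc_region =
"whole_fibre"`); a membrane-band-only alternative (`"pm_band"`) is a
config switch, since "colocalization with the membrane border" is
ambiguous between the two. Fibre typing thresholds the cohort's per-fibre
MHC1 means with an exact two-class Otsu split (no histogram binning, which
for small cohorts can return a cut inside the low class); if the split is
not clearly bimodal (high-class mean < 2x low-class mean) a configured
fallback cut is used with a warning.

## Statistics

Per-fibre measurements are the rows; repeated measurement within a
participant (three biopsies, ~30 fibres each) is handled solely by a
subject-level random intercept, fitted by REML (Gaussian mixed model).
Fixed effects come from group, infusion, timepoint, fibre type and layer.
Count responses are modelled as `log1p(count)` inside the Gaussian model —
the variance-stabilising choice that keeps the whole battery in one model
family; a Poisson GLMM would be the natural alternative and the transform
is a config switch. Singular fits and non-convergence are flagged on the
result, never silently dropped.

Post-hoc pairwise contrasts between factor levels are differences of
marginal-mean design rows (valid under interactions), with t reference on
residual degrees of freedom — Satterthwaite approximations are not
available for this fitter, and the df used is recorded in the output —
and Bonferroni adjustment across the factor's pairs. Factor-level omnibus
tests are Wald F-tests on the factor's fixed-effect columns.

On null simulations at study scale (20 subjects, 30 fibres per timepoint)
the 5% timepoint test holds its level (measured type-I error ~5% over 200
replicates), and planted effects are recovered with near-nominal CI
coverage.

## Synthetic data generator

The generator emulates the study's imaging conditions at two levels.

**Pixel level.** A fibre boundary is a smooth star-shaped closed curve
(low-order Fourier radius, radius 13–16 µm, ≥ 2 µm field margin) — not a
circle, so segmentation is exercised on realistic geometry. Per-layer spot
counts are Poisson; size classes are Bernoulli with the condition's small
fraction; radial placement is uniform within the layer band **inset by
1 px from each band edge**, with a minimum centre separation of half the
summed diameters plus 3 px. The inset and separation exist because the
generator's purpose is recovery testing: a spot centred exactly on a band
boundary, or two spots whose thresholded footprints merge, has no
well-defined recoverable layer/count, so the scene model keeps planted
truth resolvable by construction. For the same reason planted diameters
avoid the 1 µm class boundary (small 0.4–0.8 µm, large 1.3–2.0 µm): at
0.2 µm/px, single-pixel area quantization makes the class of a ~0.85–1.3 µm
spot ill-defined.

Rendering: the dystrophin channel is a ridge of Gaussian cross-profile
(FWHM = 3 px) along the boundary; the MHC1 channel is uniform inside the
fibre at a bimodal per-type level; the GLUT4 channel is a diffuse
intracellular level plus spots rendered as uniform disks of the planted
diameter convolved with a Gaussian PSF (sigma 0.1 µm). The disk⊗PSF
profile has its half-maximum exactly at r = D/2 (FWHM equals the planted
diameter) while keeping the measured size nearly independent of where the
participant threshold lands — a pure Gaussian profile dilates ~20% at
realistic thresholds and systematically misclassifies near-boundary sizes.
Insulin-stimulated membrane insertion is modelled as a GLUT4 component
sharing the dystrophin ridge profile whose amplitude is solved per image
(bracketed root-find) so the noiseless GLUT4–dystrophin correlation equals
the condition's target PCC; realized noisy-image PCC tracks the target to
within ~0.5%. Poisson photon noise and Gaussian read noise are applied
last and intensities are clipped to 16 bits.

**Measurement level.** `simulate_measurements` samples per-fibre
measurement tables directly from the same condition rates, with subject
random intercepts on log rates and log intensities and an additive subject
shift on PCC. This is the fast path used to validate the statistics at
full study scale (rendering ~1800 images per replicate would add nothing
to what the pixel-level recovery suite already establishes).

**Planted study conditions** (the generator's defaults): baseline PCC 0.50
(trained) / 0.44 (sedentary); a 0→2 h PCC rise of +2% in trained (both
infusions), +9% in sedentary-lipid and +4% in sedentary-glycerol,
maintained at 6 h; a 20% decline in small-spot rate at the membrane and
layer 1 from 2 h to 6 h; PM spot composition 99% small in trained vs 95%
in sedentary (97% of all spots small in trained); and a type II over
type I GLUT4 intensity excess of 7% (trained) / 12% (sedentary). Absolute
per-layer spot rates are free parameters of the scene model (25 at the PM,
declining inward), as absolute counts are not a quantity the assay pins
down. The default design is 2 groups x 2 infusion arms x 5 subjects per
cell, three timepoints (0, 2, 6 h), 30 images per timepoint.

**What the phantoms do not emulate:** 3-D structure, spectral
bleed-through, stage drift, staining chemistry, spatial heterogeneity of
the diffuse background, or clustered/overlapping vesicles below the
resolution limit. Passing recovery tests therefore demonstrates the
correctness of the measurement pipeline under the stated forward model,
not robustness to every artefact of real microscopy.

## Numerical choices and degenerate inputs

- Distance-map sign comes from polygon rasterization; pixels within half a
  pixel of the contour may sign-flip, which only moves them within the
  membrane band.
- Otsu ties take the first maximiser; thresholds are integer levels (float
  images are rounded).
- PCC requires ≥ 2 pixels and nonzero variance in both channels; constant
  channels raise an error rather than returning NaN.
- An all-background image, a constant pooled histogram, a single-subject
  study and an empty measurement table all raise typed errors.
- Pipeline runs are deterministic given inputs; the only randomness in the
  package is in the generator, which takes an explicit seeded generator.

## Problem sizes

The validation suite uses 50 rendered fibres (256x256 px) for spot
recovery, 64x64 grids for exhaustive distance-map checks, 20 randomized
histograms for the threshold oracle, and 50 effect/200 null replicates of
the 20-subject study for the statistics; the acceptance script reports the
same quantities at 30 fibres and 20/100 replicates. These sizes put
Monte-Carlo error comfortably below the tolerances being checked.

## Known limitations

- The centroid rule biases large membrane spots toward layer 1 (see above).
- Residual-df p-values are mildly liberal relative to Satterthwaite for
  small subject counts; at ≥ 20 subjects the difference is negligible.
- The PCC target mechanism calibrates the noiseless correlation; heavy
  noise regimes attenuate realized PCC slightly (<1% at default noise).
- `layer_origin="midline"` changes band definitions; recovery guarantees
  are stated for the default inner-edge origin.
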