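# Methods

This note documents the models and measurement procedures implemented in
`wellquant`, the parameter defaults and why they were chosen, what the
synthetic generator does and does not emulate, and the numerical choices
that matter for reproducing its results.

## Measurement model

### Coordinates and units

All geometry is in micrometres; rasters carry a `pixel_size` (µm/px,
default 0.65, typical of a 10× objective with a standard camera) and
conversion happens only at the render/measure boundary.  The origin is the
centre of the top-left pixel, x rightward, y downward, 0-based indices;
centroids are reported at sub-pixel precision in µm.  Rescaling a raster
and its `pixel_size` jointly leaves µm-domain results unchanged up to
interpolation error.

### Background subtraction

Intensity metrics are computed once per channel on background-corrected
rasters.  Two generic modes are provided: `flat_percentile` subtracts a
scalar percentile of the image, and `rolling_ball` subtracts a
morphological background field (the image is downscaled, grey-opened with
a disk of the given radius — default 50 px, which must exceed the size of
real foreground objects — smoothed and resampled; the shrink-open-upscale
scheme is the standard fast implementation of the rolling-ball idea).
The pipeline default, `geometric_median`, estimates each image's average
background as the median intensity over pixels outside the known tissue
regions (the well disc plus the control annulus) and subtracts that
scalar; for a flat background under symmetric noise the median is an
unbiased estimator, and a scalar subtraction is exactly what the
downstream normalisation step assumes.

### Nucleus segmentation

Nuclear ROIs come from the DAPI channel: Otsu threshold → removal of
debris below a quarter of the minimum area → distance-transform watershed
(peak separation default 4 µm, about one nucleus radius) to split
touching nuclei → per-label expansion.  The expansion step matters: the
thresholded core of a Gaussian-profiled nucleus of width σ and peak A has
radius σ·√(2·ln(A/t)) at threshold t, smaller than the 2σ nuclear
footprint, and intensity ROIs must *encompass* the nucleus or the
cytoplasmic compartment is contaminated with nuclear signal.  The default
`expand_um="auto"` inverts that relation per nucleus and grows each label
to its own estimated full radius (background pixels are assigned to their
nearest core, so neighbours cannot be swallowed); a fixed distance in µm
can be supplied instead.  Minimum ROI area is 20 µm² (excludes debris).
Externally curated label rasters can be injected, bypassing thresholding,
so a manual workflow remains representable.

### Zonal quantification

`equal_area_zones` uses the closed form r_k = R·√(k/K) (default K = 4).
Zone membership is by centroid with half-open boundaries [r_{k−1}, r_k),
the outermost zone closed at R; nuclei with r > R are flagged outside and
excluded from zone summaries.  Densities are count / annulus area in
cells/mm².  Conservation (Σ zone counts + outside = all nuclei) is a
tested invariant.

### N:C ratio and control normalisation

The cytoplasmic compartment of a colony is the actin tissue mask
(Otsu + closing + hole fill, intersected with the well disc) minus the
nuclear ROIs; N:C = mean nuclear / mean cytoplasmic intensity, per nucleus
and pooled per colony.  The pipeline additionally excludes a one-pixel
perinuclear ring from the cytoplasmic compartment
(`cyto_exclusion_px = 1`): partial-volume pixels at the nuclear boundary
otherwise bias the cytoplasmic mean upward and the ratio downward by a
few percent.  Well-level nuclear means are normalised to nuclei found in
the surrounding unconfined control annulus (default from R+20 µm to
R+120 µm, configurable); 1.0 means equal to the unconfined monolayer.
Both N:C and the normalised intensity are invariant under any positive
global gain, which is a tested property.

### Actin architecture

The radial profile is the pointwise mean over 8 full diameters at 22.5°
increments through the well centre (16 half-lines), sampled at 1 px
spacing with bilinear interpolation, then folded to 0..R by averaging
symmetric points.  Whether the source workflow's "8 intersecting lines"
were diameters or radii is not stated anywhere; diameters are the natural
reading and double the averaging.  Classification replaces a qualitative
visual call with explicit criteria: with C the profile mean over the
inner 30 % of R, E over the outer 20 % and M in between, a profile with
coefficient of variation below `flatness_cv` (default 0.15) is *uniform*;
otherwise E/max(C, M) > `contrast_threshold` (default 1.25) ⇒
*peripheral*, C/max(E, M) > threshold ⇒ *central*; remaining profiles get
the larger of C and E with a `weak` diagnostic.  The defaults separate
the three generator archetypes with 100 % accuracy noise-free and ≥95 %
at 10 % amplitude noise, and classification is invariant under gain.

### High cells and clusters

PDX1-high cells are defined by a population-derived threshold — by
default mean + 2·sd of the background-subtracted nuclear means, with
percentile and absolute modes available, because positive-cell
frequencies depend strongly on this choice and it must stay a visible
sensitivity knob.  Clusters are single-linkage components of the flagged
centroids (edge iff distance ≤ `linkage_radius`, default 30 µm ≈ two cell
diameters; groups below 5 cells discarded), implemented as connected
components of the KD-tree proximity graph and verified in tests against a
brute-force union-find oracle.  Cluster geometry (area, equivalent-circle
diameter, circularity 4πA/P²) is measured on the convex hull of member
centroids; note the hull of points sampled inside a disc underestimates
the disc diameter by ~5–10 % at the cell counts involved, which is within
the 15 % recovery band used in validation.

### Statistics

Multi-group comparisons use one-way ANOVA followed by Tukey's HSD
(scipy); two-group comparisons use Student's t-test, equal-variance by
default with Welch behind a flag.  Star tiers follow the unusual
convention of the source figure legends: n.s. ≥ 0.05, * < 0.05,
** < 0.01, *** < 0.005, **** < 0.001.  The ANOVA entering the pipeline's
tables compares per-well colony values (cell-level means per well), not
pooled cells.  The modality-consistency control takes paired per-cell
intensities from two imaging modes and declares them consistent iff the
per-cell ratio CV is below 0.15 (configurable — the underlying judgement
is "a constant ratio", which needs a numeric bound) and an intercept does
not significantly improve on a through-origin linear fit.

## Synthetic generator

The generator emulates the statistical structure the measurements assume,
with full ground truth:

* **Geometry.**  Circular colonies of 150/300/500 µm diameter on a canvas
  with a 10 µm margin, optionally surrounded by an unconfined control
  ring (20 µm gap, 100 µm wide, 1500 cells/mm²) that provides the
  in-image normalisation reference.
* **Cells.**  Default overall densities 3000/2500/2000 cells/mm² for
  150/300/500 µm wells (density falls with diameter after 72 h of
  confined culture), distributed over the K = 4 equal-area zones with
  default weights (0.40, 0.30, 0.20, 0.10) — concentrated in the inner
  zones.  Zone assignment is exact multinomial; positions are uniform in
  area within the zone, with a 0.75 µm guard band at interior zone
  boundaries (and one nucleus radius at the colony edge) so that
  ground-truth zone membership is robust to sub-pixel centroid error.
  Nucleus radii are normal (mean 4 µm, sd 0.4 µm) truncated at ±2 sd;
  placement rejects centres closer than `min_separation` × the summed
  radii (default 0.6; recovery studies that require individually
  resolvable nuclei use 1.1–1.2) with up to 1000 retries before a packing
  error.
* **Channels.**  DAPI nuclei are isotropic Gaussians truncated at 3σ with
  σ = radius/2.  TF channels are flat at `tf_nuclear_mean` inside each
  nucleus disc and at `tf_nuclear_mean`/`tf_nc_ratio` over the rest of
  the colony, so the rendered raster has an exactly known N:C.  Actin
  follows one of three archetypes: uniform (constant), peripheral
  (constant + Gaussian ring at 0.95 R, width 0.08 R), central (constant +
  Gaussian cap, width 0.3 R).  Background is additive (default 10 a.u.)
  and noise is additive Gaussian (unclipped, so the background median
  stays unbiased).
* **Monolayers.**  Confluent fields with Poisson (or fixed) cell numbers;
  cells inside `n_clusters` discs of 150 µm default diameter carry TF
  intensity × `high_intensity_fold` (default 3); an optional
  `high_fraction` adds sporadic high singletons.
* **Modality pairs.**  A second image equal to gain × the noise-free
  signal plus fresh noise, with shared truth, for the constant-ratio
  control.

What the generator does **not** emulate — and hence what passing recovery
tests cannot show about real data: optical blur beyond the Gaussian blob
model (no PSF convolution), multilayered/3D colonies (rasters are 2D
projections; the bulged morphology of small wells is invisible here),
intensity heterogeneity within a nucleus, autofluorescence gradients,
shading/vignetting, and segmentation difficulty of truly confluent
overlapping nuclei.  Recovery results bound algorithmic error, not
biological or optical error.

## Cohort simulation for the significance pattern

The end-to-end statistical check builds cohorts with the study's group
sizes — 21/13/9 wells for 150/300/500 µm plus 12 unconfined fields — and
true N:C elevated only in the two smaller diameters (2.25/1.95 vs 1.5).
Each well's true N:C is drawn log-normally around its group mean with a
10 % well-to-well coefficient of variation, reflecting the substantial
colony-to-colony biological variability such experiments show; without
it, per-well measurement noise is so small that sub-percent bias
differences between the confined and unconfined measurement geometries
would dominate the comparison.  Confined and unconfined groups are
measured through the same path without background subtraction (a
confluent field has no cell-free pixels to estimate background from, and
the shared raw-intensity path keeps the two geometries' biases matched).
The configured pattern — 150 µm and 300 µm significant vs control under
Tukey, 500 µm not — is recovered in well over 90 % of replicates.

## Problem sizes

Validation suites run at desk scale: counting recovery uses 12 seeds ×
3 diameters (36 wells) in tests and 10 × 3 in the acceptance script; N:C
recovery 15 wells per level (12 in the script); actin classification
10 seeds × 3 classes × 3 diameters per noise level (8 in the script);
the ANOVA null calibration 2000 simulations; the significance-pattern
study 40 cohort replicates in tests and 30 in the script.  Cohort and
classification renders use 1.3 µm/px sampling (still ≥ 57 px across the
smallest well).  These sizes keep every recovery estimate's sampling
error comfortably inside the tolerance it is checked against.

## Known limitations

* The automated nuclear ROIs replace the source workflow's manual ROI
  selection; the `labels=` injection path exists precisely so curated
  ROIs can be swapped in.
* Whether per-region intensities should be background-corrected per
  region rather than per image is undecidable from the available
  description; correction is per image here.
* The convex-hull cluster diameter is biased low for sparse clusters (few
  member centroids near the true boundary).
* `rolling_ball` is a fast approximation (shrink–open–smooth–upscale),
  not an exact rolling-ball; with radii ≫ object size the difference is
  negligible relative to the 5 % recovery check it must satisfy.
* Well geometry is taken from image metadata or config; the optional
  Hough-style auto-detection of well centres is not implemented — layouts
  must be supplied.
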