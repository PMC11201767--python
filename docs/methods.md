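# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `zonequant`. Everything stated here is computed by the
test suite or by `scripts/acceptance.py`; nothing is asserted from data the
package cannot regenerate.

## Tissue model and zonation geometry

A cortical column is modeled as a ribbon between two polylines: the pia
boundary `y = A·sin(2πx/width)` and the white-matter boundary, its vertical
translate by `depth`. Normalized depth d ∈ [0, 1] is 0 at the pia and 1 at
the white matter; because the white matter is a vertical shear of the pia,
the ribbon area is exactly `width × depth` for any curvature amplitude A
(constrained to A < depth/4 so the ribbon stays ribbon-shaped).

Zonation follows the field procedure: connecting lines are drawn between the
two boundaries at equal **arclength fractions** (the only parameter-free
reading of "evenly spaced" that generalizes to curved cortex), each line is
split by its endpoints plus five equidistant interior points, and matching
points on adjacent lines are joined by straight segments to bound six simple
polygons. Zone 1 abuts the pia, Zone 6 the white matter. Whether the original
procedure joined marked points with straight segments or traced curves is not
determinable from its description; straight segments are used. The number of
columns per section defaults to 4 (configurable) — the procedure's sources do
not state one.

Cells are assigned to zones by centroid point-in-polygon (shapely), scanning
zones in pia-to-white-matter order so a centroid exactly on a shared boundary
goes to the lower (pia-ward) zone; this makes assignment deterministic and
order-independent. Centroids outside all zones are "unassigned" (index 0) and
are excluded from summaries with a logged count. In a rectangular column this
reduces to half-open depth bands: zone = ceil(6·d) with bands
[(k−1)/6, k/6).

## Synthetic cortex generator

The generator is a first-class, tested component, not a fixture. It encodes
the statistical structure the analysis is designed to detect:

- **Damage-probability profile.** p(z) = clip(a + b·z + c·z², 0, 1) on the
  integer zone index (the analysis's unit, not continuous depth). AD default
  (0.0201, 0.0955, −0.010612): vertex 4.5, peak 0.235, p(1) = 0.105, zone
  mean 0.1934. UC default: flat 0.055. The AD/UC mean ratio is 3.52,
  inside the three- to four-fold band the profiles were calibrated to.
- **Case heterogeneity.** One random intercept per case on the logit of p
  (sd 0.15), producing between-case scatter comparable to case-level SEM
  error bars without shifting the mean appreciably (the logit-scale Jensen
  bias is +0.06 pt for UC, +0.1 pt for AD).
- **Cell placement.** Uniform in the ribbon, optionally with a hard-core
  minimum spacing (default 8 µm) enforced by rejection sampling on a spatial
  hash grid, capped at 50× oversampling attempts before a packing error.
  Positivity and zone statistics do not depend on packing, so large
  statistical simulations may set `min_spacing=0` for speed.
- **Nuclear sizes.** Neuron/glia log-normal mixture: fraction 0.4 neurons,
  component means 79 and 28 µm², log-sd 0.25 — larger neuronal nuclei with
  overlap between the classes.
- **53BP1 intensity.** Log-normal with damage-dependent log-mean
  (µ− = ln 30, µ+ = ln 120, σ = 0.25, arbitrary units) plus a shallow size
  tilt κ·(area − mean area), κ = 0.05 a.u./µm². Only ratios and correlations
  of intensities are meaningful; the a.u. scale is arbitrary.
- **p16 coupling.** For damage-positive cells,
  p16 = α + s·z + β·53BP1 + ε with α = 10, β = 1, and the depth slope s
  shared with the damage-negative model (AD 3 a.u./zone, UC 0). The noise is
  scaled to the coupled signal: SD(ε) = ratio·|β|·SD(53BP1 among positives),
  which makes the asymptotic r² of p16 on 53BP1 equal to 1/(1 + ratio²)
  conditionally on zone — 0.722 at the AD ratio 0.62 and 0.281 at the UC
  ratio 1.60. Pooling across zones adds the depth-trend variance to the
  noise and lowers the AD value to ≈ 0.709; both values sit well inside the
  ±0.10 band the coupling checks use. Damage-negative cells carry
  baseline 25 + s·z + Gaussian noise (sd 8); cytoplasmic p16 is
  18 + 0.8·z + noise (sd 5) in both conditions. The depth slope is applied
  to the positive subset as well as the negative one because the positive
  subset's depth profile is itself an analysis output; a model without it
  would make that analysis trivially null.
- **Rendering.** Each nucleus is an isotropic Gaussian blob with
  σ = 0.5 × equivalent radius and peak amplitude proportional to the channel
  intensity (DAPI amplitude constant at 300, independent of marker status),
  over a constant background of 20 with Poisson shot noise. Default synthetic
  pixel size is 0.5 µm/px (the acquisition-scale 0.325 is configurable);
  a pixel budget guards against accidentally huge rasters.
- **Culture.** γ-H2AX-positive probabilities 0.05 / 0.18 / 0.38 for control /
  1 µM / 10 µM etoposide (the 1 µM value is an interpolation between the
  calibrated endpoints), p27-positive probability 0.15 everywhere, three
  replicates per condition. Flags are drawn first and intensities from
  strictly sub-/supra-threshold distributions, so positive counts are exactly
  binomial and flags are exactly threshold-consistent. p27 intensity is drawn
  independently of γ-H2AX.

What the generator does **not** emulate: amyloid plaques and tangles, 3-D
tissue and z-stacks, optical point-spread beyond the Gaussian blob,
uneven illumination, autofluorescence, segmentation-hostile nuclear shapes,
or a condition difference in total cell density. Passing tests therefore
validate the pipeline's correctness and calibration on data obeying the
stated model — they do not certify detection accuracy on real slides.

## Detection and measurement

Detection is Gaussian smoothing (σ 1 µm, converted to pixels), a global
threshold, hole filling, distance-transform watershed splitting (peak
separation 4 µm), and an area filter (5–400 µm²). The automatic threshold is
Otsu on the smoothed image: for blob-shaped foregrounds the pixel histogram
has no flat plateau, so a histogram-valley threshold lands between blob
shoulders and peaks and drops the dimmer nuclei; Otsu recovers them (the
valley method remains available as `threshold_method="valley"`, and a
foreground-fraction guard returns zero labels when a supposed tissue image
thresholds to more than 30% foreground, which only happens on
foreground-free noise). Per-cell positivity classification, by contrast,
uses the histogram-valley threshold on the per-cell nuclear means, whose
distribution is genuinely bimodal. Positivity is a strict inequality
(mean > threshold); a cell exactly at the threshold is negative.

The pseudoplasm annulus assigns every background pixel within the expansion
distance (default 5 µm) to its nearest nucleus by Euclidean distance, so
annuli never overlap and exclude nuclear pixels. Equidistance ties go to the
lower label id, implemented by running the exact EDT in two scan orders
(forward and 180°-flipped) and taking the smaller label where they disagree;
this is exact for pairwise ties, and higher-order ties on a pixel grid are
both vanishingly rare and still deterministic. Intensity means are computed
on raw (not smoothed) pixels. Coordinates are 0-based pixel indices, origin
top-left, x rightward, y downward, physical = index × pixel size
(pixel-center convention).

## Statistics

- Depth-profile regressions use the integer zone index as abscissa, with one
  observation per case × zone (fractions as the primary response; per-mm²
  densities are also reported since the published unit is ambiguous).
- adjusted r² = 1 − (1 − r²)(n − 1)/(n − k − 1); the quadratic fit reports
  the vertex −b/(2c) (missing when c = 0). Model comparison is the partial F
  test for the added quadratic term with (1, n − 3) df, with preference by
  adjusted r².
- The condition × zone ANOVA uses Type II sums of squares on case × zone
  summaries — appropriate for the unbalanced 4-vs-3-case design; a constant
  response reports zero sums of squares with missing F.
- Unpaired t-tests are pooled-variance by default (Welch by flag); no
  multiple-testing correction is applied, matching the raw-p-value
  convention of the source analyses.
- Size-ranked profiles sort by nuclear area (ties broken by cell id), chunk
  into bins of exactly 100 cells, drop the remainder, and regress bin mean
  intensity on bin rank. With exactly two bins the slope has no residual df
  and the fit is reported as missing.
- The coupling regression samples up to 100 damage-positive cells per case
  without replacement (seeded); a case with fewer eligible cells contributes
  all of them with a logged warning, and a case with none is an error.
- Culture statistics use the replicate as the unit for SEM and t-tests, and
  per-cell regressions within conditions for the p27-vs-γ-H2AX scatter.

## Calibration simulations and their sizes

The property suites run at sizes chosen for statistical adequacy:

- Quadratic-vertex recovery: 200 AD cohorts of 4 × 5000 cells; the fitted
  vertex falls in (4, 5) in ≥ 95% of runs.
- UC flatness: 500 UC cohorts at 300 cells/case. The zero-slope test on 18
  case × zone points is only calibrated (rejection ≈ α) where per-zone
  binomial noise dominates the between-case random effect; at the default
  5000 cells/case the case effect inflates the residual MSE ≈ 2× and the
  test becomes conservative (~1% rejection). The calibration therefore runs
  in the binomial-dominated regime; this is a property of zone-level
  regression on clustered data, not of the implementation.
- ANOVA null calibration: 2000 replicates of iid-normal responses on the
  4-vs-3 design, condition-effect rejection 5% ± 1.5 pt at α = 0.05.
- Detection: precision and recall ≥ 0.95 against ground truth on a rendered
  200-nucleus field, and per-zone positive-fraction recovery within 3 pt on
  a rendered 1200-cell column.
- Zone assignment agrees exactly with an independent crossing-number oracle
  on 10,000 random points in a curved column; zone areas are additive to
  1e−6 relative tolerance.

## Reproducibility

Every stochastic stage takes an explicit seed; cohort and pipeline seeds are
expanded with `numpy.random.SeedSequence.spawn`, so identical configurations
yield byte-identical tables, rasters and reports (asserted in the suite). The
pipeline writes a manifest with a configuration hash and per-stage outputs.

## Known limitations

- No machine-learned segmentation, stain deconvolution, 3-D handling, or
  whole-slide pyramid I/O; boundaries (pia/white matter) are inputs, never
  segmented from images.
- No mixed-effects or spatial-autocorrelation modeling; case-level clustering
  enters only through the simulation design and the case × zone summaries.
- The 4-case AD cohort mean damage fraction is itself a random quantity
  (sd ≈ 1.35 pt across seeds); single-cohort numbers should be read with
  that in mind.
- Whether per-cell intensity means should be computed on raw or smoothed
  pixels is unspecified in the procedure this follows; raw pixels are used.
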