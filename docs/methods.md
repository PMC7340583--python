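# Methods

This note documents the models and procedures implemented in `wallquant`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data tests do and do not demonstrate about real data.

## Image pipeline

### Acquisition model and axis conventions

Fields are 3-channel Z-stacks with axes (channel, section, row, column),
channels addressed by name (mCherry, Citrin, CFP; stored in that order in
stacks written by this package), 0-based indices throughout. The nominal
acquisition this emulates is 28 optical sections at a 300 nm axial step on
an sCMOS camera; neither value is asserted — both are plain metadata
(`SceneSpec.image_shape`, `voxel_step_z`) and the pipeline works for any
stack with at least one section.

### Sum projection

The stack is collapsed by per-pixel summation over sections before any
segmentation, in float64 so 16-bit integer stacks cannot saturate.
Everything downstream — masks, thresholds, intensities — lives in this
projected 2-D space; all "pixel" counts are projected pixels. A
consequence worth keeping in mind: every projected pixel contains the
camera offset once per section (28 × 100 = 2800 ADU at the defaults), and
wall intensities are chord-length weighted (a pixel at the cell rim sums a
long tangential path through the wall shell).

### Cell segmentation

Foreground is a global threshold of the Citrin + CFP projection (every
cell carries exactly one cytosolic marker, so their sum is cell-filled),
followed by hole filling, removal of objects below `min_object_pixels`
(default 64), optional distance-transform watershed splitting of touching
cells (seeds from distance-map maxima at least `split_min_distance = 10`
pixels apart), and optional removal of border-touching cells (default on:
their wall band is truncated and would bias the wall mean). Labels are
relabeled consecutively in raster-scan order, which makes repeated runs
bit-identical.

The default threshold is the **triangle** method rather than Otsu. The
intensity histogram of these projections is a dominant near-constant
background peak with a long foreground tail, and the projected cytosol
falls off continuously at the cell rim (the axial chord through the
cytosol shrinks to zero there). Otsu, which balances two broad classes,
settles mid-slope and systematically shrinks masks — measured IoU against
ground-truth footprints was 0.85 on noiseless scenes. The triangle
threshold sits at the foot of the background peak and recovers footprints
exactly (IoU 1.0 noiseless, ≥ 0.99 at the default noise level). Otsu and a
fixed threshold remain selectable (`threshold_method`). Both automatic
methods are invariant to adding a constant to all channels.

### Cell-wall band

The wall of a cell is the set of its pixels whose Euclidean distance to
the nearest non-cell pixel is ≤ `wall_width`; the interior is the
complement within the cell. The distance criterion (rather than erosion by
a square structuring element) keeps the band width rotation invariant.
Pixels of a touching neighbour count as "outside", so clumped cells get a
wall along their shared boundary. Wall and interior partition the cell
mask exactly — this accounting identity is asserted in tests for every
cell. Cells whose interior erodes away entirely are flagged degenerate and
excluded from measurement.

Default `wall_width` = 3 px. At the ~65 nm/px sampling implied by a 100×
objective on an sCMOS chip this is ≈ 200 nm, a plausible optical width for
the yeast cell wall; tests pass for widths 2–5, and measurement accuracy
against ground truth is best when the width matches the generative shell
thickness.

### 2-D versus 3-D

Segmentation and measurement run in the sum projection by default, i.e.
projection precedes segmentation. This matches the ordering of the
pipeline stages and the magnitude of the default cell-size filter
(2400–55,000 pixels is a projected-area scale for yeast at ~65 nm/px; a
3-D voxel count would be an order of magnitude larger). The wall-band rule
(`boundary_band`) is dimension-agnostic and operates on 3-D masks as well,
but the supported, tested path is 2-D.

### Per-cell measurement, volume filter, classification

For each cell and channel the minimum, maximum and integral intensity are
recorded separately over the wall and interior pixel sets (float64
accumulation; raw, unnormalized values). Cells pass the size filter iff
`volume_min ≤ interior_pixels ≤ volume_max`, a **closed** interval with
defaults [2400, 55,000]; both boundary behaviours are tested
explicitly.

Identity: a cell is *reference* iff its interior Citrin maximum exceeds
the Citrin threshold while its interior CFP maximum stays below the CFP
threshold, *tester* for the mirror image, and *unclassified* otherwise —
both inequalities strict, so a value exactly at a threshold never
classifies. Thresholds default to 200 ADU. Unclassified
cells are excluded from statistics but written to the cell table flagged,
so exclusion is auditable. The channel-to-identity mapping follows the
strain construction (reference strain expresses cytosolic Citrin, testers
CFP); a `swap_identity_channels` switch inverts it for data with the
opposite convention.

Two thresholds, one subtlety: the 200-ADU thresholds describe fluorescence
*above background*, but a summed raw stack carries the camera offset once
per section in every pixel (2800 ADU at the defaults), which would leave
every cell unclassified. `quantify_field` therefore estimates a
per-channel background level as the median projected intensity over
cell-free pixels and subtracts it from the interior maxima before
thresholding. Recorded per-cell intensities stay raw. Classification is
thereby invariant to the camera offset, which also preserves the
channel-swap symmetry (swapping the two cytosolic channel images swaps
reference ↔ tester for every classified cell). On deconvolved input —
where background is already ≈ 0 — the correction is a no-op.

### Field statistics

Per-field summary over classified cells: group means ± s.d. (n−1) of the
per-cell mean wall mCherry, the normalized ratio (tester mean / reference
mean — arithmetic means of per-cell means), and a two-sided Mann–Whitney
*U* test. The exact null distribution is used when both groups have ≤ 20
cells, the midrank/tie-corrected normal approximation above that; both
branches are exposed and agree to ≤ 0.01 in p at n = 20 (tested over 100
random cases), and the asymptotic branch is calibrated (null rejection
rate at α = 0.05 within [0.04, 0.06] over 2,000 simulated fields of 80 + 80
cells). Group sizes below `min_n` (default 80, the acquisition target)
warn rather than fail.

## Synthetic scenes

Cells are ellipsoids; the cytosolic marker fills the interior (the full
ellipsoid minus a shell of `wall_thickness`), and the mCherry wall signal
occupies the shell, either uniformly or restricted to a crescent cone of a
given half-angle about an axis (half-angle 180° degenerates to the uniform
shell, and every crescent mask is a subset of the uniform one — both are
tested properties). Cells may be truncated by the image border; centers
must lie inside. Overlapping cells raise an error unless an explicit
`overlap_tolerance` permits clumps (used to exercise watershed splitting).

Noise model, applied voxel-wise to the noiseless signal S:

    value = Poisson(S · g) / g + Normal(0, σ_read) + offset

with `poisson_scale` g in photons/ADU (0 disables shot noise) and
`gaussian_sd` σ_read in ADU (0 disables read noise); noisy stacks are
rounded and clipped to the 16-bit range, noiseless stacks stay exact
floats. This is first-order sCMOS behaviour. Defaults: offset 100 ADU,
σ_read = 2 ADU, g = 1 — a raw-frame regime. Scenes standing in for
*deconvolved* input (the regime the quantification was designed for
upstream) use offset 0, since deconvolution removes the offset; tests that
probe statistics through the full pipeline do so. A single integer seed
drives one generator per call, so every scene is bit-reproducible.

What the generator does **not** emulate: the microscope point-spread
function (no blur — mask edges are geometrically sharp), photobleaching,
stage drift, buds and bud scars, autofluorescence, or spectral bleed
between channels. Passing tests therefore demonstrate the correctness of
the *accounting* — segmentation, band carving, intensity sums,
classification and statistics — not robustness to optical artefacts of
real stacks.

Ground truth for measurement tests is defined operationally: the
segmentable footprint of a cell in the projection is its projected
interior (only the cytosol is marked, so nothing outside it is visible to
the cell threshold), and `true_mean_wall_mcherry` is the noiseless
projected mCherry (offset included) averaged over the boundary band of
that footprint at the cell's generative wall thickness — exactly the
quantity the pipeline estimates. On 50 seeded noiseless scenes the
pipeline recovers cell counts exactly, footprints at IoU ≥ 0.9, the
accounting identity exactly, and the wall mean within 5%.

## Ligand binding

One-site model on total ligand, B(L) = B_max·L/(K_d+L) + c·L, the standard
free ≈ total approximation. Background (protein-free) series are
subtracted point-wise by default, matching how such controls are run; a
linear slope can be co-fit instead. Because purified protein (~100 pmol)
and ligand (100–500 pmol) can be comparable, a depletion-corrected mode
solves the binding quadratic for the complex exactly
(C² − C(P+L+K_d) + PL = 0) behind a flag; it reduces to the hyperbola as
P → 0 (tested).

Estimation is unweighted nonlinear least squares (trust-region, positive
bounds) with default starts K_d = median(L), B_max = max(B); standard
errors from the Jacobian. Degenerate inputs error early: fewer than 3
distinct ligand points, all-zero signal, non-convergence. When the largest
ligand concentration lies below the fitted K_d the fit converges but
attaches a "weak-saturation" warning — such designs barely constrain K_d.
Noiseless model data are recovered to ≤ 1e-6 relative across K_d 1–200 µM;
the fit is invariant to point order, and uniform rescaling of the signal
rescales B_max while leaving K_d unchanged.

Units: ligand inputs are treated as concentrations in the declared unit
(default µM) and K_d is reported in that unit. Assay tables reported in
pmol require the user to supply the assay volume to convert; the package
does not guess it.

Uncertainty at the reference design: with 8 single-determination points
spanning 0.2–4 × K_d and absolute Gaussian noise of 5% of B_max, the
Cramér–Rao bound puts the relative standard error of K_d at ~25%, and the
least-squares fit tracks it (median single-curve error ~16%). No estimator
does materially better at that design; what *is* tight is the bias — the
median fitted K_d across 200 Monte-Carlo repeats lands within ~1% of the
generative value, and that across-repeat median is the quantity the
recovery experiments (`simulate_kd_recovery`, `scripts/acceptance.py`)
report, with a 10% acceptance band.

## Mating assays

Mating efficiency per replicate = diploid colonies (double selection) /
total colonies (single selection); the synthetic generator draws diploids
Binomial(total, efficiency). A condition is summarized as mean ± sample
s.d. (n−1) over replicates; comparisons against a named baseline use
Welch's t on the per-replicate efficiencies (replicate-level framing, not
pooled counts), two-sided, p from Student's t at Welch–Satterthwaite df.
Four identical replicates compared to themselves have zero variance in
both groups and error out rather than fabricating a p-value. Significance
stars: `***` p < 0.001, `**` p < 0.01, `*` p < 0.05, `n.s.` otherwise, all
strict.

## Problem sizes in the test suite

Synthetic fields in the suite are 12 × 200 × 200 to 12 × 300 × 300 voxels
with 2–6 cells — large enough that cells pass the default 2400-pixel
interior floor where the pipeline's defaults are under test, and small
enough that the whole suite (196 tests, including the 50-scene oracle
sweep, 2,000-field null calibration and 600 Monte-Carlo binding fits) runs
in ~10 s. Statistical assertions use fixed seeds and tolerances stated
inline (binomial/normal standard-error bands, 10% medians).

## Known limitations

- No point-spread-function simulation: segmentation accuracy on real,
  blurred stacks will be below the synthetic IoU ≈ 1.0; the triangle
  threshold's advantage over Otsu on sharp-edged synthetic data should be
  re-examined on deconvolved real data.
- The wall band is morphological (a fixed-width rim of the cytosol
  footprint), not an mCherry-intensity-derived segmentation; wall signal
  displaced more than `wall_width` pixels from the cytosol boundary is
  missed.
- 2-D measurement after projection discards axial localization; polarized
  caps oriented along the optical axis project onto the footprint center,
  not the rim.
- Binding fits assume homoscedastic noise (unweighted least squares) and a
  single site; cooperative or two-site data will fit poorly without
  warning beyond residual inspection.
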