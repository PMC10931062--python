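# Methods

## Coordinate and label contract

A segmentation volume is an integer array `[bscan, depth, ascan]` with one
label per voxel: 0 background, 1 retina (ILM→Bruch's membrane, BM), 2 IRF,
3 SRF, 4 PED. Axis 0 is the slow axis (en-face *y*), axis 2 the fast axis
(en-face *x*), axis 1 depth. B-scan *i* sits at `i · isd_um`, so the scan
positions span the slow-axis FOV inclusively and `(n_bscans − 1) · isd_um ==
fov_y_um` is enforced. A-scan column *i* sits at `i · pitch_x` with
`pitch_x = fov_x_um / n_ascans`. Geometry is always taken from an explicit
JSON sidecar, never inferred from NIfTI/TIFF headers, which vary by
exporter. Laterality normalization (mirroring left eyes so +x points nasal)
is an analysis step, applied by `enface.mirror_if_left`, never at I/O time.

Single-label voxels are a deliberate simplification: clinically, biomarker
masks may overlap, but a one-label volume keeps containers simple and every
per-biomarker operation already takes a biomarker argument (a *label set*,
e.g. IRF∪SRF = {2,3}, total retina = {1,2,3}), so a multi-mask backend would
only touch the I/O module.

## Default geometry

49 B-scans × 496 depth samples × 480 A-scans over 6 × 6 mm, ISD 125 µm,
7 µm axial sampling — the common dense raster protocol of a Spectralis-class
device. 480 A-scans (rather than 512) makes the in-plane pitch exactly
12.5 µm, so the 250 µm crop step of the FOV analysis is exactly 20 pixels
and crop boundaries carry no rounding ambiguity. All geometry fields are
configurable.

## Synthetic cohorts

The generator emulates the statistical structure the analyses rely on, not
OCT appearance:

* **Anatomy.** BM is a gently tilted plane (per-eye jitter ±30 µm offset,
  ±40 µm tilt) at 62% of the axial extent; retinal thickness is 300–340 µm
  with a Gaussian foveal depression (100–140 µm deep, σ 350–450 µm), giving
  an ILM surface with a central pit. Only label geometry matters downstream.
* **Presence.** Per eye and biomarker, presence is an independent Bernoulli
  draw from the disease preset: AMD — IRF 0.25, SRF 0.55, PED 0.90;
  RVO — IRF 1.0, SRF 0.42, PED 0.0.
* **Spatial structure.** A positive eye carries `1 + Poisson(1)` ellipsoidal
  lesions whose en-face centers are Normal(fovea, σ_pop²) truncated to the
  FOV. σ_pop defaults to 800 µm, which puts most occurrence mass inside the
  central 3 mm ETDRS ring; the RVO preset uses σ_pop = 1200 µm for IRF,
  reflecting its flatter, less fovea-peaked distribution.
* **Lesion shape.** En-face semi-axes 100–500 µm, axial semi-axes 50–200 µm,
  uniform. No quantitative lesion-size distribution is available for these
  cohorts, so these are plausible defaults, exposed in `DiseasePreset`. The
  lower bound of 100 µm means small lesions can fall entirely between
  B-scans once the effective ISD reaches 250 µm, which is what produces the
  early sensitivity loss the ISD analysis is designed to measure.
* **Placement.** IRF ellipsoids are centered at 30–70% of local retinal
  thickness and clipped to the slab; SRF ellipsoids are centered on BM and
  clipped to the slab (their upper halves fill the subretinal space); PED
  ellipsoids are centered on BM and keep only the part below it (a dome
  displacing BM outward). Labels are painted PED, then SRF, then IRF, so a
  later compartment overwrites earlier ones at conflicts. If overwriting
  ever erases an intended-positive biomarker completely, the eye's lesion
  plan is redrawn from the same stream (bounded retries); per-eye positivity
  therefore matches the Bernoulli draw exactly.
* **Reproducibility.** Eye *i* of a cohort uses the substream
  `SeedSequence(seed, spawn_key=(i,))`: byte-identical output for a fixed
  config, any eye regenerable in isolation, no order dependence.

What passing tests on these cohorts show — and do not show: they validate
the *pipeline* (projections, crops, decimation arithmetic, fit behavior)
under controlled conditions where ground truth is known. They do not certify
clinical sensitivity values: real fluid is not ellipsoidal, lesion sizes and
counts are disease- and treatment-dependent, and real cohorts carry grader
noise. Quantities like "sensitivity at 2×2 mm" transfer qualitatively, not
numerically.

## Heatmaps and the Gaussian fit

Per-eye presence maps (any biomarker voxel in a depth column ⇒ 1; the
threshold is presence-only by design, with a `min_column_voxels` hook) are
averaged into a fraction-of-eyes heatmap over the eyes aggregated — the eye
is the aggregation unit throughout. The isotropic model
`A·exp(−((x−μₓ)²+(y−μᵧ)²)/(2σ²))` is fit by trust-region least squares over
all pixels in physical µm (the two axes have pixel pitches of 12.5 µm and
125 µm, so index-space fitting would distort σ). Initialization is
parameter-free: A₀ = max, (μₓ₀, μᵧ₀) = intensity-weighted centroid, σ₀ =
weighted RMS radius / √2. Bounds A ∈ [0, 1.5], μ within the FOV ± σ₀,
σ ∈ (0, max FOV extent] keep the optimizer off degenerate plateaus. Pixels
are weighted equally; on the regular grid every pixel covers the same
physical area, so the `area_weighted` flag cannot change the result there
and exists for irregular future grids. R² uses SS_tot about the heatmap
mean; a constant heatmap has SS_tot = 0 and is reported as R² = NaN with
`converged=False`; an all-zero heatmap is rejected as undefined. On
non-convergence the best iterate is still reported with `converged=False`.

## FOV crop sensitivity

The map is indexed by crop *size* on a 250 µm grid, with every crop centered
on the FOV center: scans are macula-centered and the fovea is taken to be
the FOV center (no per-eye fovea localization). A sliding-window variant
(fixed size, varying position) would answer a different question and is out
of scope. Crop rectangles are closed intervals — a pixel exactly on the
boundary counts as inside — evaluated with a 1e-9 relative tolerance so the
convention survives float rounding; with the default geometry all boundary
comparisons are exact anyway. Sensitivity uses reference-positive eyes only
as the denominator; eyes negative in the full FOV cannot affect the map.
Because centered crops are nested, the map is provably non-decreasing along
both size axes — asserted, not assumed, in tests. The optimized
implementation maps each presence pixel to the smallest centered crop
containing it and accumulates a per-eye detection frontier; it is exactly
equivalent to re-scanning every crop, and tests verify exact equality
against that brute force.

## ISD decimation, volumes, MAPE

Decimation by a power-of-two factor *f* keeps B-scans {0, f, 2f, …, n−1};
both borders are always retained, which is the only phase consistent with
border half-weighting, and requires *f* | (n_bscans − 1) — satisfied by the
49-scan protocol for f = 1, 2, 4, 8 (125→1000 µm). Volume is the slice sum
Σᵢ aᵢ·wᵢ with aᵢ = (voxel count in scan i) · pitch_x · depth_scale (µm²) and
wᵢ = ISD for interior scans, ISD/2 at the two borders, so Σ wᵢ = fov_y
exactly at every level: a constant-cross-section structure gets exactly the
same volume at every decimation. The in-plane voxel area factor yields true
µm³; it cancels in every relative quantity (sensitivity, MAPE), and is
included purely for interpretability. No interpolation between B-scans is
performed — the estimator is deliberately the piecewise-constant one a
device's own software effectively uses.

Detection sensitivity at a level is per eye: a reference-positive eye counts
as detected iff any retained B-scan contains the biomarker. MAPE is
`mean(|V_ref − V_reduced| / V_ref) · 100` over reference-positive pairs;
pairs with V_ref = 0 are excluded from both the sum and n (the percentage is
undefined) and their count is reported. Total retinal volume uses labels
{1,2,3} (ILM→BM includes intraretinal and subretinal fluid); PED lies below
BM and is excluded. The streaming implementation reduces each eye to
per-B-scan voxel counts — sufficient statistics for both detection and
volume — and tests verify exact equality against decimate-then-measure.

## Orchestration and determinism

`run_all` makes streaming passes over a manifest (geometry homogeneity
enforced), emits per-biomarker prevalence, heatmap + fit, FOV map and ISD
tables into one `summary.json` (floats rounded to 10 decimals, keys sorted:
reruns on identical inputs are byte-identical), CSV tables in the MAPE-table
layout with `n/a` for biomarkers without reference-positive eyes, and
renders figures (ETDRS overlay at 1/3/6 mm diameters, per-biomarker color
scales, red squares at the exemplary crop sizes, relative-volume boxplots)
as non-fatal side effects.

## Problem sizes in the test suite

Unit and property tests run on a reduced 13 × 64 × 96 grid with the same
6 × 6 mm FOV and axial extent, chosen so decimation factors 2 and 4 remain
valid; statistical and oracle-equivalence checks use default-geometry
cohorts of 50–500 eyes with fixed seeds (50 for exact brute-force
equivalence, 200 for monotonicity and ordering suites, 500 for prevalence
and Gaussian parameter recovery at exact binomial 99% confidence). The
acceptance script uses 80 AMD and 12 RVO eyes, the cohort sizes of the
reference clinical protocol.

## Known limitations

* Ellipsoidal single-compartment lesions; no multifocal irregular fluid,
  no co-located multi-label pathology, no grader disagreement model.
* Fovea fixed at the FOV center for cropping; no per-eye localization.
* The Gaussian model is isotropic by definition; anisotropic or rotated
  fits are out of scope.
* Volume estimation is piecewise-constant in the slow axis; no
  interpolation-based estimators.
* R² of occupancy heatmaps depends on cohort size (small cohorts are
  noisier), so fitted R² values are cohort statistics, not biomarker
  constants.
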