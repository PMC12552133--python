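# Methods

This note documents the models and procedures implemented in `spheroquant`,
the parameter choices that matter, what the synthetic data does and does not
emulate, and the package's known limitations.

## Phantom and optics forward model

A spheroid phantom is a sphere of radius *R* (µm) with a uniform nuclear
intensity and, per marker channel, a radial concentration function *c*(*r*)
on normalized radius *r* ∈ [0, 1]:

| family | definition | emulates |
|---|---|---|
| `uniform` | *c* = 1 | nuclear counterstain; fully penetrated carrier |
| `outer_shell(r0)` | 1 for *r* ≥ *r₀* | rim-localized proliferation (Ki-67-like, *r₀* = 0.8 → outer 20% of radius); thin matrix shells |
| `inner_core(r0)` | 1 for *r* ≤ *r₀* | core-localized apoptosis/hypoxia |
| `penetration_front(f_pen, s)` | logistic step at *r* = 1 − *f*<sub>pen</sub>, width *s* | a carrier that has diffused the outer *f*<sub>pen</sub> of the radius |

The front softness default *s* = 0.02 (normalized radius) exists purely to
avoid aliasing a hard step on the pixel grid; at *s* = 0 the step is exact.
Rasterization uses the pixel/voxel-center rule with no anti-aliasing.

Section images evaluate *c* at the pixel's 2D normalized radius. Z-stacks
evaluate *c* at the voxel's 3D normalized radius and multiply by a
detection-attenuation factor exp(−*p*/*λ*), where *p* is the tissue path
length from the sphere's upper surface to the voxel along the optical axis
z (z increases with depth, as on an inverted microscope) and *λ* is the
modality's attenuation length:

- `clsm` preset: *λ* = 50 µm, so usable signal vanishes by ~100–150 µm of
  tissue — the phenomenological depth limit of confocal imaging of
  uncleared/cleared-but-scattering 3D samples;
- `lsfm` preset: *λ* = 1000 µm, near-uniform detection through an optically
  cleared ~0.5 mm spheroid;
- `ideal`: no attenuation.

These are simulator parameters chosen to reproduce the qualitative depth
phenomenology, not measured optical constants; no measured attenuation
lengths for cleared spheroids were available to fit. The model deliberately
omits PSF physics along z, refractive-index mismatch and pinhole optics: it
is the smallest forward model that produces the confocal-vs-light-sheet
discrepancy with a known ground truth. An optional lateral Gaussian blur
(`lateral_psf_sigma`, default 0) is available.

Noise is Poisson shot noise at `poisson_scale` photons per intensity unit
(default 200; the draw is rescaled so the expected value is unchanged) plus
additive Gaussian read noise (`gaussian_sigma`, default 0.01 intensity
units) — the standard fluorescence-camera model. All generators consume a
single integer seed through `numpy.random.default_rng` and are
bit-reproducible.

Growth series render a darker disk on a brighter background (transmitted-
light contrast) with Gaussian noise; the diameter follows a constant,
linear, or logistic closed form. Defaults (500 → 1000 µm over 10 days,
sampled daily) match the growth regime the analysis targets.

What the synthetic data does **not** emulate: textured or debris-laden
backgrounds, irregular/lobed spheroid outlines, nucleus-scale intensity
granularity, scattering anisotropy, bleaching, or z-dependent PSF widening.
Passing tests therefore demonstrate correctness of the *procedures* under
controlled conditions, not robustness to every artifact of real microscopy;
segmentation thresholds and the nuclear-mask percentile are the knobs to
revisit on real data.

## Morphometrics

Segmentation: global Otsu threshold on the inverted image (spheroid darker
than background; a constant offset is available for low-contrast frames),
hole filling, morphological opening (disk radius 2 px), largest connected
component. An empty mask raises an error rather than returning nothing, and
a mask occupying ≥ 50% of the image border is rejected as unreliable.

Metrics: area is pixel count × pixel area. Perimeter uses the 4-direction
Crofton estimator, which is close to unbiased on smooth rasterized shapes —
the common weighted-boundary-step estimator overestimates a disk's
perimeter by ~5%, dragging circularity 4π·A/P² down to ~0.90 for a perfect
disk; with Crofton a rasterized disk of radius ≥ 50 px scores 0.99–1.00.
Circularity uses the perimeter *squared* in the denominator, the
dimensionally consistent definition for which a disk scores 1. Aspect ratio
is the major/minor axis ratio of the second-moments ellipse (scikit-image
`regionprops`), hence ≥ 1 by construction. "Diameter" is the
equivalent-area diameter 2·√(A/π), which is robust to boundary noise;
caliper (Feret) diameters were deliberately not used for growth curves.

Growth curves segment each timepoint independently; a failed timepoint is
recorded as missing (NaN), never interpolated, and the series fails only if
every timepoint does.

## Radial profiling

The pipeline fixes the finalization order as: per-sector binning → average
over sectors → divide by maximum → 5-point centered moving average (window
truncated at the sequence ends, no padding). Details and rationale:

- **Center**: intensity-weighted centroid of the Otsu-thresholded nuclear
  channel. The same center serves all sectors ("the segment's center" is
  read as the common section center).
- **Sector edge radius**: 99th percentile of nuclear-pixel radii per 30°
  sector — the maximum is hostage to single stray nuclei. A sector with no
  nuclear pixels is flagged degenerate and excluded from averaging (the
  profile fails only if *all* sectors are degenerate).
- **Binning**: 100 uniform bins on normalized radius [0, 1]; pixels beyond
  their sector's edge radius are discarded. The per-bin statistic is the
  **mean** intensity: a per-bin *sum* scales with annulus area and
  confounds radial shape with abundance (the sum is available via
  `statistic="sum"` for sensitivity checks). Empty bins (common near r = 0,
  where annuli contain few pixels) are filled by linear interpolation from
  neighboring bins before averaging.
- **Nonnegativity**: the averaged profile is clipped at 0 — read noise can
  push near-zero bin means slightly negative, and intensities are
  physically nonnegative.
- **Normalization**: division by the profile maximum, so the peak is
  exactly 1 whenever any positive signal exists; an all-zero profile stays
  zero and records `peak_intensity = 0` so downstream code can recognize
  signal-free channels.

For z-stacks, the nuclear threshold is computed **once, globally over the
whole nuclear volume**, not per section: under strong depth attenuation the
deep sections contain only noise, and a per-section Otsu would segment that
noise as a large spurious mask — corrupting both the section-area ranking
and the choice of representative section. With a global threshold, deep
sections correctly yield small or empty masks and are skipped (mask area
< 10% of the maximal section's). The representative profile is the
maximal-area (equatorial) section's.

## Penetration

The radial penetration fraction is read from the finalized profile by the
half-maximum front rule: the penetrated zone is the outer contiguous run of
bins with smoothed normalized intensity ≥ threshold (default 0.5), scanned
inward from r = 1; the fraction is 1 minus the *inner edge* of the last bin
of the run (inner edge rather than bin center, so a run covering exactly
the outer 20 of 100 bins reads 0.200 and a full run reads 1.000). The run
ends at the first sub-threshold bin. No above-threshold bin at the edge →
0; a signal-free profile → 0. The threshold is scale-free (the profile is
max-normalized), mandatory, and recorded in every `PenetrationResult`.

Volumetric conversion: *V* = 1 − (1 − *f*)³, exact for a spherical
geometry with a sharp front.

Penetration is measured on the representative equatorial-section profile by
default. An alternative 3D spherical-shell profile (binning voxels by 3D
normalized radius) is provided (`spherical_shell_profile`) and agrees with
the sectionwise estimate on unattenuated stacks; it is inappropriate under
confocal-like attenuation, where deep voxels carry no signal.

`modality_bias_experiment` chains simulate → profile → estimate for each
(phantom, modality, seed) and tabulates estimated vs true fractions with
signed errors. At the default study conditions (250 µm radius, 4 µm pixels,
10 µm z-step, default noise) the ideal-modality estimates recover known
fronts essentially exactly, the light-sheet model recovers a fully
penetrated phantom at volumetric ≥ 0.9, and the confocal model
underestimates it by ≥ 0.2 — the in-silico reproduction of the
confocal-vs-light-sheet disagreement, with the simulator providing the
ground truth that real experiments lack.

## Response statistics

Relative viability divides each well's luminescence by the mean of the
vehicle-control wells; no blank subtraction by default (a `blank_label`
option subtracts cell-free wells first). The per-dose summary is
mean ± SD over replicates. Cytotoxicity is
100 × (signal − background)/(lysis − background), clipped at 0; both
statistics are invariant to positive rescaling (viability) and affine
transformation (cytotoxicity) of the luminescence scale.

Dose–response fits use the descending four-parameter logistic
y = bottom + (top − bottom)/(1 + (dose/IC50)^hill), parametrized in
log₁₀ IC50 for optimizer stability (bounds: hill ∈ [0.1, 10], log-IC50
within the tested range ± 2 decades), fit by least squares to **individual
replicate wells** rather than per-dose means — with only ~8 dose means a
4-parameter sigmoid can fit monotone-looking noise and fake a response,
whereas replicate-level residuals keep R² honest; fitting replicates is
also the default in standard curve-fitting software. Dose 0 (vehicle) is
excluded from the fit and used only for normalization. "No IC50" is
declared when the optimizer fails, the fitted IC50 falls outside the tested
dose range (never extrapolated), or R² < 0.8; the R² cutoff operationalizes
"not a well-defined sigmoid", is configurable, and is recorded with the
verdict. At the simulated study conditions (8 doses spanning 1 nM–10 µM,
3 replicates, 10% CV) the fit recovers IC50 with median |log₁₀ error|
≈ 0.04 over 100 plates and the no-IC50 rule fires on 100% of flat-response
plates.

The diameter–viability correlation is the standard Pearson product–moment
coefficient (scipy), reported with n and the two-sided p-value; inputs with
zero variance are rejected.

## Pipeline and reproducibility

`RunConfig` (pydantic) validates every parameter before any stage runs —
thresholds in range, injective channel map, odd smoothing window.
`run_pipeline` derives one sub-seed per stage from the top-level seed
(`numpy.random.SeedSequence`), executes stages in order, halts downstream
stages on failure while preserving completed outputs, and writes a
`manifest.json` (config, seed, version, per-stage status and outputs) from
which the run is reproducible. Images are plain multipage TIFF; tables are
UTF-8 CSV with period decimals; ground truth travels in schema-versioned
JSON sidecars. No stage mutates its inputs on disk.

## Problem sizes in the validation suite

The test suite validates penetration recovery on 250 µm-radius phantoms at
4 µm lateral sampling and 10 µm z-step (≈ 51 sections of 135×135 px, two
channels), 10 seeds per condition; the dose–response properties on 100
simulated plates per scenario; and morphometrics on disks of 50–200 px
radius. These sizes were chosen as the smallest at which the discretization
errors are clearly below the tolerances being asserted.

## Known limitations

- The optics model is phenomenological: a single exponential attenuation
  per modality, no PSF along z, no scattering model. It reproduces the
  direction and rough magnitude of confocal depth bias, not instrument-
  specific numbers.
- Sector edge radii from a 99th-percentile rule track the local boundary
  only as finely as the sector width; strongly elliptical sections need
  more than 12 sectors for accurate per-direction edges.
- Segmentation assumes one spheroid per field, darker than the background;
  multi-spheroid tracking, invasion/outgrowth quantification, and nucleus
  instance segmentation are out of scope.
- The penetration estimator assumes a monotone-ish front near the edge; a
  marker that is genuinely brighter in the core than at the edge (e.g. a
  core-localized stain) has no penetration interpretation and reads 0.
- Plate parsing is generic long-format CSV only; no vendor formats.
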