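# spheroquant

Quantitative image analysis for 3D tumor-spheroid experiments.

Spheroids — scaffold-free spherical aggregates of cancer (optionally plus
stromal) cells — are the workhorse in-vitro model for solid-tumor biology and
nanomedicine screening. Their readouts are overwhelmingly image-based, and
several of the standard analyses are easy to get subtly wrong: shape metrics
depend on the perimeter estimator, radial biomarker statistics are biased by
non-circular sections, and — most consequentially — confocal microscopy's
~100 µm depth limit makes intact-spheroid penetration measurements look far
shallower than they are. `spheroquant` implements these analyses carefully
and ships a synthetic phantom/optics simulator so that every stage can be
validated against known ground truth.

## What it computes

**Morphometrics** (`spheroquant.morphometrics`) — segment a spheroid from a
label-free (brightfield/Incucyte-style) image and report, in physical units:

- area *A*, perimeter *P* (Crofton estimator), equivalent-area diameter
  2·√(*A*/π),
- circularity 4π·*A*/*P*² (1 for a perfect disk),
- aspect ratio = major/minor axis of the moments-based best-fit ellipse,
- growth curves: diameter vs time, failed timepoints recorded as missing.

**Radial profiling** (`spheroquant.profiling`) — the sectorized radial
intensity profile of a stained section: the section is split into 12 sectors
of 30° around the nuclear-weighted centroid; each sector's edge radius comes
from the nuclear (DAPI) counterstain (99th percentile of nuclear-pixel
radii); pixel radii are normalized per sector; per-bin mean intensities are
averaged over sectors, max-normalized, and smoothed with a centered 5-point
moving average. `profile_zstack` applies this to every optical section of a
3D stack and reports the maximal-area (equatorial) section as representative.

**Penetration** (`spheroquant.penetration`) — from a finalized profile, the
radial penetration fraction *f* is the outer contiguous run of bins at or
above half-maximum (threshold 0.5, configurable and always logged), and the
volumetric penetration is the spherical shell-volume fraction

&nbsp;&nbsp;&nbsp;&nbsp;*V*(*f*) = 1 − (1 − *f*)³,

so a front spanning the outer 73.8% of the radius already fills 98.2% of the
volume, and 41.7% of the radius fills 80.2%.

**Response statistics** (`spheroquant.response`) — relative viability
(normalized to vehicle controls), cytotoxicity as percent of detergent-lysis
maximum, four-parameter-logistic dose–response fits with an explicit
"no IC50" verdict (optimizer failure, IC50 outside the tested range, or
R² < 0.8 — never extrapolated), and the Pearson correlation between spheroid
diameter and viability.

**Simulator** (`spheroquant.phantom`) — parametric spheroid phantoms
(uniform, outer-shell, inner-core, and penetration-front radial
concentration profiles), label-free growth series with closed-form diameter
models, and multichannel z-stacks imaged through a minimal optics forward
model: expected voxel intensity = concentration × exp(−tissue path along
z / attenuation length), plus Poisson shot noise and Gaussian read noise.
Presets mimic confocal detection (attenuation length 50 µm) and light-sheet
imaging of optically cleared samples (1000 µm).

## Worked example: why confocal imaging misreads penetration

A 250 µm-radius phantom fully and uniformly penetrated by a fluorescent
nanocarrier (true radial fraction 1.0), imaged under both forward models and
analyzed with the identical pipeline:

```python
import spheroquant as sq

phantom = sq.SpheroidPhantom(
    radius=250.0, pixel_size=4.0,
    marker_profiles={"nanocarrier": sq.penetration_front(1.0)},
)
for name in ("clsm", "lsfm"):
    stack, truth = sq.make_zstack(phantom, sq.MODALITY_PRESETS[name], seed=42)
    zp = sq.profile_zstack(stack, channel_name="nanocarrier")
    result = sq.estimate_penetration(zp.representative, threshold=0.5, source=name)
    print(f"{name}: radial = {result.radial_fraction:.3f}, "
          f"volumetric = {result.volumetric_fraction:.3f} "
          f"(truth: radial 1.000, volumetric 1.000)")
```

prints

```
clsm: radial = 0.330, volumetric = 0.699 (truth: radial 1.000, volumetric 1.000)
lsfm: radial = 1.000, volumetric = 1.000 (truth: radial 1.000, volumetric 1.000)
```

The light-sheet model recovers the truth; the confocal model — identical
specimen, identical analysis — loses the carrier signal exponentially with
tissue depth and reports a spurious shallow front. This is the in-silico
version of the well-documented failure mode of using confocal z-stacks to
judge nanocarrier penetration in intact spheroids.
`sq.modality_bias_experiment(...)` runs this comparison systematically over
phantoms, modalities and seeds and returns a tidy table.

## Command line

```bash
spheroquant simulate zstack --seed 1 --out run/         # phantom + ground truth
spheroquant morpho frames/*.tif --pixel-size 4 --out morpho.csv
spheroquant profile run/zstack.tif --segments 12 --bins 100 --out run/
spheroquant penetration run/zstack.tif --threshold 0.5 --out pen.csv
spheroquant benchmark-modality --seeds 10 --out bias.csv
spheroquant response plate.csv --out resp/
spheroquant run config.yaml --seed 1 --out run/         # full pipeline + manifest
```

Every run writes a `manifest.json` with the config, seed, package version
and per-stage status, and is reproducible from that manifest alone.

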