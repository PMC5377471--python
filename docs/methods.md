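# Methods

`bioturbaton` measures how sediment-dwelling invertebrates rework
particles, build biogenic structures and irrigate their burrows, and
provides the statistical machinery used to compare species' functional
effects. Every measurement stage is exercised end-to-end on synthetic data
whose ground truth is known by construction; this note records the models,
the defaults and the reasoning behind the open design choices.

## Particle reworking from profile images (f-SPI)

A sediment aquarium photographed through a transparent wall under UV light
shows fluorescent tracer particles (luminophores) against a darker sediment
matrix. The chain is:

1. **Tracer detection** — an HSV window around the tracer colour
   (default: saturated magenta, hue 5/6 ± 0.10, saturation ≥ 0.40, value
   ≥ 0.25) followed by removal of true pixels with no 8-neighbour.
   Single-pixel sensor noise is thereby discarded while real particles,
   which span ≥ 2 pixels at 56 µm resolution, survive. An empty mask is a
   legal result, reported as an explicit missing-value record.
2. **Interface tracing** — per column, the first row (top-down) whose
   luminance exceeds a threshold (Otsu's split of the image luminance by
   default; the water column is far darker than the matrix), then a
   median filter across columns (window 11) to suppress single-column
   artefacts. If more than half the columns have no supra-threshold pixel
   the image is rejected as degraded rather than silently summarised.
3. **Metrics** — each tracer pixel's depth is its row minus the *local*
   interface elevation of its column, clamped at 0 above the interface,
   times the pixel size; `L_med`, `L_mean`, `L_max` are the median, mean
   and maximum of that depth list and `SBR` is the relief (max − min) of
   the valid interface elevations. All lengths are reported in cm.

Open choices, resolved as follows: depths are referenced to the local
interface (a global plane would bias the shallow statistics whenever SBR is
nonzero); metrics are computed over tracer *pixels*, i.e. area-weighted,
because particle identity is not recoverable from a photograph; `L_max` is
taken after the isolation filter because a single order statistic is
maximally sensitive to noise; the composite faces of one aquarium are
analysed as a single concatenated image yielding one record per aquarium.

## Burrow morphometrics from CT volumes

Gray level in a reconstructed CT volume tracks bulk density: bright =
sediment, dark = burrow lumen. Segmentation is threshold-based seed-point
region growing: a voxel belongs to a seed's burrow system iff its gray
value is ≤ the threshold and it is 6- or 26-connected to the seed.
Internally the maximal connected components are computed with
`scipy.ndimage.label` and mapped to seeds; labels are assigned in seed
order so the segmentation is deterministic, and seeds falling in one
component merge. The default connectivity is 26 because thin oblique
burrow segments fragment under 6-connectivity. The default threshold is
Otsu's split of the below-interface gray histogram; `auto_seed` places one
seed per sub-threshold component that reaches below the sediment surface
(components confined to the overlying water are excluded) and exceeds a
minimum size.

Metrics:

* `B_vol` is exact: labelled voxel count × voxel volume.
* `B_SA` is the area of a marching-cubes iso-surface (level 0.5) of the
  labelled indicator after Gaussian smoothing with σ = 1 voxel. Smoothing
  matters: on a binary mask the staircase artifact inflates a sphere's
  mesh area by ~9%, while the smoothed mesh is within ~1% for radii ≥ 15
  voxels (and −0.9% for a radius-20 test cylinder). By default the faces
  capping burrow openings at the sediment surface are excluded — an
  opening is water, not burrow wall — by replicating the surface-layer
  void voxels upward so the mesh never closes over an opening, then
  discarding triangles above the local surface plane; `include_openings`
  reverses this.
* `B_max` is the maximum voxel depth below the local surface elevation
  (per-(y,x) map, flat-plane fallback), counting the voxel's lower face,
  consistent with the f-SPI depth convention.

Volumes of more than 8 bits are linearly rescaled to 0–255 on ingest.

## Bioirrigation

Δ[Br⁻] = end − start concentration of an inert bromide tracer in the
overlying water (mg L⁻¹), optionally minus a faunal-free control drift;
more negative values mean stronger irrigation. No normalisation by
duration or water volume is applied by default (the statistic is an
absolute change over a fixed 8 h window); a per-hour option exists.

## Observed yield (D_max)

Responses are first mapped to a performance scale: identity when larger
is more function, negation when more-negative is more function (the
bromide drawdown). Per mixture replicate,
`D = (P_mix − best) / |best|` where `best` is the largest monoculture mean
performance; the estimate is the replicate mean with a Student-t 95% CI.
`D_max > 0` is transgressive overyielding, `< 0` underyielding. The
per-replicate-then-average construction (rather than a bootstrap on
treatment means) was chosen to match the replicate-level ±95% CI reporting
style of small balanced designs; division by |best| keeps the sign
convention meaningful even for negative performance scales.

## Heteroscedastic GLS (varIdent)

The inference engine fits `y = Xβ + ε`, `ε_i ~ N(0, σ²_ref · r²_g(i))`
with one free sd ratio per variance-group level (reference ratio = 1).
The fixed effects and σ_ref are profiled out: given log ratios, β is
weighted least squares with weights 1/r² and σ²_ref has a closed form, so
only the g−1 log ratios are optimised (BFGS, warm-started from the
OLS-residual group sds, Nelder–Mead fallback; non-convergence is flagged,
never silent). ML and REML log-likelihood conventions match `nlme::gls`;
`scripts/crosscheck_gls.py` demonstrates agreement of logLik, AIC, β, σ,
sd ratios and standard errors to better than 1e−4 on a shared fixture.
Standard errors always use the df-corrected residual variance
(RSS_w/(n−p)) regardless of estimation method, again following the
reference implementation; t tests use df = n − p. AIC counts p fixed
effects + (g−1) ratios + σ_ref.

Model selection follows the standard sequence for this model family:

1. variance structure chosen by REML AIC between the homoscedastic and
   varIdent fits with the full fixed structure (REML likelihoods are
   comparable only at fixed mean structure);
2. fixed terms deleted backwards under ML, dropping the weakest term while
   its deletion p ≥ α. When both candidate models are homoscedastic OLS
   the deletion test is the exact F test; otherwise the χ² likelihood
   ratio test. The exact test matters at this design scale: at n = 20 the
   χ² LRT for a 3-df factor rejects a true null ~9% of the time at
   α = 0.05, the F test exactly 5%;
3. final refit by REML. Every candidate's AIC is recorded in the trace.

The χ² reference for the *variance-structure* REML LRT is also only
asymptotic: at 4 groups × 5 replicates its simulated null rejection rate
at α = 0.05 is ≈ 0.066 (a Bartlett-type small-sample inflation), which the
acceptance checks verify lies in [0.03, 0.08].

## Synthetic generators

The generators emulate the study conditions of a 4-treatment (three
monocultures + equal-biomass mixture) × 2-core-shape × 5-replicate
mesocosm experiment: square cores 8.86 × 8.86 × 15 cm and circular cores
⌀10 × 15 cm share a 1178 cm³ habitat volume, and 1 g of biomass per square
footprint is ≈ 127 g m⁻².

**Profile images.** A rough interface (smoothed Gaussian random walk with
prescribed relief, default 0.15 cm) separates dark water from a gray
matrix. The final generator step median-filters the interface with the
same window the detector uses, so the rendered surface is median-stable
and its relief is an exact ground truth for SBR. Tracer particles are
1 × 2-pixel blobs (a < 125 µm particle spans about two 56 µm pixels);
single-pixel tracers would be indistinguishable from the sensor noise the
detector is required to remove, and 2-row blobs could not honour the
degenerate all-depths-zero case. Routine burial depths are half-normal
(scale = archetype mixing depth); a small deep-transport fraction (default
2%) rides burrow tracks down to the archetype's burrow depth. This
two-component kernel is a modelling choice, not a measured profile: it
reproduces the qualitative contrast between surficial routine mixing
(L_med) and rare deep events (L_max), but no claim is made that real
depth profiles are half-normal. Depths are sampled once per particle and
only the *column* is re-drawn on placement collisions — resampling the
depth too would bias the accepted distribution away from the crowded
surface (a ~+9 SE bias at 10⁴ particles before this was fixed). Every
placed pixel's depth, computed with the same local-interface convention
as the pipeline, is recorded as ground truth.

**Burrow volumes.** Burrows are carved as voids (gray 25) in a bright
matrix (gray 200, Gaussian noise sd 8 by default), all opening at the
surface slice. Three carving archetypes mirror the study species' burrow
morphologies: correlated-random-walk branched galleries descending to
~7.5 cm (Poisson branching along the trunk), paired-limb U-tubes to
~2.6 cm, and straight vertical shafts to ~3.3 cm (carved as exact
discrete cylinders, which gives an analytic oracle). Target depths are
drawn in [0.85, 1] × the archetype depth so the depth ordering
gallery > shaft > U-tube holds with margin. The mixture is the union of
the three archetypes with burrow counts scaled by ⅓. The exact carved
voxel set is recorded before noise. The default test voxel size is
0.05 cm — coarser than the scanner's 81 µm — so a full-depth gallery fits
in a ~160-slice volume; acquisition-scale geometry (81 µm voxels) is used
where the analytic cylinder checks need it.

**Experiment tables.** One row per aquarium, response = treatment mean +
core-shape effect + N(0, σ_treatment). Default treatment means are on the
observed 8 h bromide-loss scale (−486.79, −383.42, −359.83, −346.90
mg L⁻¹ for HD/CV/Mix/HU, with −325.20 for circular vs square cores when a
shape effect is requested).

What the generators deliberately do **not** emulate: camera optics and
stitching, CT projection physics and reconstruction artefacts (beam
hardening, rings), tidal or photoperiod activity rhythms, diagenesis, and
any time-resolved behaviour. Passing tests therefore demonstrate the
correctness of the measurement and inference chain, not robustness to
every real-world imaging artefact.

## Archetype defaults

| archetype | mixing scale (cm) | burrow depth (cm) | radius (cm) | burrows | Δ[Br⁻] rate (mg L⁻¹ h⁻¹) |
|---|---|---|---|---|---|
| gallery_diffuser | 0.40 | 7.5 | 0.20 | 3 | −60.85 |
| u_tube | 0.34 | 2.6 | 0.10 | 8 | −47.93 |
| i_shaft | 0.53 | 3.3 | 0.12 | 2 | −43.36 |
| mixture | 0.40 | 7.5 (union) | — | ⅓ of each | −44.98 |

Burrow depths and the irrigation rates are calibrated to the printed
ranges for the corresponding species; mixing scales are set so the
half-normal median falls in the observed 0.23–0.36 cm L_med band. The
printed per-species summary statistics under-determine full depth
profiles, so these defaults are calibrated to the metric ranges only.

## Numerical choices and degenerate inputs

* Region-growing equals exhaustive flood fill exactly (verified against a
  brute-force BFS oracle on random volumes up to 32³, both
  connectivities); raising the threshold can only grow components.
* Marching-cubes smoothing σ = 1 voxel; components smoothed below the iso
  level fall back to the unsmoothed indicator so tiny lumens still mesh.
* Empty tracer masks, empty seed lists and empty segmentations return
  explicit zero/NaN records (with a warning where a statistic is
  undefined), never exceptions.
* Variance-ratio optimisation tolerance: BFGS gtol 1e−8; homoscedastic
  fits bypass optimisation entirely and equal OLS to machine precision.
* Selection ties (equal deletion p) break toward the candidate with the
  smaller AIC.
* All generators take explicit integer seeds; the pipeline derives
  per-stage seeds from the run seed via `SeedSequence`, so a config fully
  determines every output byte.

## Problem sizes

Tests and the acceptance script run on deliberately modest sizes chosen to
exercise every code path at full fidelity: profile images of 250–300 × 1500
px (56 µm pixels, 1200–2000 particles), volumes of ~160 × 72 × 72 voxels at
0.05 cm (or 120 × 52 × 52 at 81 µm for the analytic cylinder), 1000 null
simulations for LRT calibration, 100 for selection consistency, and
n = 200/group for variance-ratio recovery (reported as the mean over 5
datasets, whose Monte-Carlo sd of ~3% sits well inside the 10% recovery
band that a single n = 200 draw would miss ~40% of the time by chance).

## Known limitations

* The GLS engine covers varIdent only — no varPower/varExp, random
  effects, or correlation structures.
* D_max is reported without an additive complementarity/selection
  partition.
* Burrow topology (branch counts, network metrics) is out of scope; only
  the three printed morphometrics are computed.
* The χ² p-values of ML likelihood-ratio tests are asymptotic and
  anti-conservative at n = 5/group; the selection routine compensates with
  exact F tests only in the homoscedastic branch.
* f-SPI tracer detection assumes the tracer colour is separable in HSV;
  heavily discoloured sediment would require a custom `ColorRule`.
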