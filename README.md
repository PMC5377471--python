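# bioturbaton

Functional-effect descriptors for sediment-dwelling invertebrates: a
tested Python pipeline for quantifying how benthic species rework
particles, build burrows and irrigate sediment, and for the statistics
used to compare those effects across species and mixtures.

Marine soft-sediment fauna mediate nutrient cycling through three coupled
mechanisms, each with its own standard measurement:

* **Particle reworking** — fluorescent sediment profile imaging (f-SPI):
  tracer particles (luminophores) spread on the sediment surface are
  photographed through the aquarium wall under UV light, and their depth
  distribution below the sediment–water interface yields the median,
  mean and maximum mixed depths (^f-SPI^L_med, L_mean, L_max) plus the
  surface boundary roughness (SBR).
* **Biogenic structure** — micro-CT: burrow lumens are segmented from
  reconstructed volumes by threshold-based seed-point region growing,
  giving burrow wall surface area (^CT^B_SA), lumen volume (^CT^B_vol)
  and maximum burrow depth (^CT^B_max).
* **Bioirrigation** — drawdown of an inert bromide tracer from the
  overlying water (Δ[Br⁻], mg L⁻¹ over 8 h; more negative = more
  irrigation).

On top of the measurements sit the two inference tools such experiments
need: the observed-yield statistic **D_max** (does a species mixture out-
or under-perform its best monoculture?) and a from-scratch
**heteroscedastic GLS** engine (varIdent variance structure, ML/REML,
likelihood-ratio tests, AIC-guided backward selection) that matches
`nlme::gls` to printed precision.

Because the measurement chain is only trustworthy if it can be checked,
the package ships first-class synthetic generators: profile images,
burrow volumes and factorial experiment tables with exact ground truth
(every tracer pixel's depth, every carved voxel, every simulated mean and
sd), emulating three functional archetypes — a deep gallery-building
polychaete, a surficial U-tube amphipod and a shaft-excavating gastropod —
plus their equal-biomass mixture.

## Worked example

```python
from bioturbaton import (archetype, make_profile_image, detect_tracers,
                         detect_interface, reworking_metrics)

image, truth = make_profile_image(archetype("gallery_diffuser"),
                                  width_px=300, height_px=1500,
                                  seed=1, n_particles=2000)
mask      = detect_tracers(image)
interface = detect_interface(image)
metrics   = reworking_metrics(mask, interface, image.pixel_size_cm)
```

Printing the four statistics (`examples/01_particle_reworking.py`) gives:

```
L_med  = 0.280 cm   (typical short-term mixing depth)
L_mean = 0.409 cm   (time-integrated mixing)
L_max  = 7.448 cm   (rare deep transport events)
SBR    = 0.151 cm   (surface relief)
```

The median depth says routine reworking is confined to the top ~3 mm of
sediment; the maximum shows that a few tracers were carried down burrow
galleries almost to the bottom of the 8 cm profile — two very different
facets of the same species' activity, which is exactly why several
descriptors are computed at once. Brute-force statistics over the
generator's ground-truth particle list reproduce all three numbers to the
pixel.

The other examples cover CT morphometrics (`02`), bioirrigation and
D_max (`03` — a mixture drawing down less bromide than the best
monoculture gives D_max < 0, i.e. underyielding), heteroscedastic GLS
with backward selection (`04`), and the full pipeline (`05`). A thin CLI
mirrors the stages:

```bash
bioturbaton simulate image --archetype u_tube --seed 3
bioturbaton fspi *.png --pixel-size-um 56 --out metrics.csv
bioturbaton ct stack.tiff --threshold auto --connectivity 26
bioturbaton gls table.csv --response response --factors treatment \
    --varident treatment --ref treatment=HD --select
bioturbaton run --seed 11 --out demo_run
```

## Layout

```
src/bioturbaton/
  synthetic.py     generators with ground truth; archetypes; geometry
  fspi.py          tracer detection, interface tracing, L/SBR metrics
  ct.py            region growing, auto-seeding, B_max/B_SA/B_vol
  bioirrigation.py Δ[Br⁻]
  yield_stats.py   D_max with t-based CI
  gls.py           varIdent GLS, LRT, backward selection
  io.py            TIFF/PNG/CSV + sidecar metadata
  pipeline.py      seeded end-to-end runs with config hashing
  cli.py           thin argparse front-end
docs/methods.md    models, defaults, numerical choices, limitations
examples/          one narrative script per capability
```
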