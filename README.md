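# hemirad

Light availability at the forest floor and in open terrain, computed from
elevation and canopy-height rasters via **synthetic hemispheric images**.

Mountains and trees control how much sunlight reaches the land surface, and
through it snowmelt, microclimate, photosynthesis and habitat suitability.
`hemirad` models this with two quantities at any point on a landscape:

* **Sky-view factor (SVF)** — the fraction of the upper hemisphere that is
  open sky, a proxy for diffuse light.  Two receiver geometries are
  provided: *SVF-planar* (a flat horizontal surface; 10° zenith rings
  weighted by their projected area, `w ∝ sin²θ₂ − sin²θ₁`) and *SVF-hemi*
  (a three-dimensional receiver such as a plant; rings weighted by their
  hemisphere surface area, `w ∝ cosθ₁ − cosθ₂`).
* **Direct-beam transmissivity (DBT)** — the time-varying fraction of the
  0.53° solar disc left unobstructed by terrain and canopy, computed on a
  2-minute solar track (NOAA solar-position equations, fixed UTC+1 civil
  time) and averaged to hourly steps — 8784 of them for the leap year 2020.

Both derive from a binary sky/obstructed image on a 1°×1°
(zenith × azimuth) hemispheric grid, built in two stages:

1. **Terrain stage** — a horizon line at 1° azimuthal increments, combining
   a local high-resolution pass (5 m DTM, 300 m radius) with a regional
   pass (50 m DTM, 25 km radius) by per-azimuth maximum.
2. **Canopy stage** — rays are marched through the canopy volume implied
   by a 1 m canopy height model; the within-crown path length `l` and the
   foliage area volume density `λ` (m⁻¹, interpolated per pixel from an
   evergreen/deciduous mix-rate raster, with leaf-on/leaf-off variants and
   an alpine-larch override) set the Beer–Lambert transmission
   probability

   `p = exp(−G Σ λ·l)`,  `G = 0.5` for randomly oriented foliage,

   which is binarised (seeded-stochastic or thresholded) and intersected
   with the terrain image.

Surface shortwave radiation follows from the two quantities and
above-canopy forcing: `SWR_i = SWR_dir,i·DBT_i + SWR_dif,i·SVF`, with the
potential-flux ceiling `I₀·cos θ·τ_atm` (`I₀ = 1361 W m⁻²`) available
when no forcing is measured.

A forest mask (0 = no run, 1 = forest, 2 = open) drives the orchestration:
every modelled pixel gets a terrain-only layer; forest pixels additionally
get leaf-on and leaf-off layers.  SVF ships as single-band GeoTIFFs and
hourly DBT as daily NetCDF files, both 8-bit percent encoded (0–100).

## Worked example

A point at the centre of a 30°-rim crater holding a mixed (30 % evergreen)
gapped forest; hourly DBT for 21 June 2020:

```python
import datetime
import numpy as np
from hemirad import (ModelConfig, SceneSpec, make_scene, plan_run, run_point,
                     ForestMask)
from hemirad.pipeline import PipelineInputs

spec = SceneSpec(terrain_kind="crater", forest_kind="gapped", extent=300.0,
                 rim_angle_deg=30.0, crater_radius=80.0, crown_height=15.0,
                 crown_width=4.0, crown_density=0.02, evergreen_fraction=0.3,
                 seed=7)
scene = make_scene(spec)
local, regional = scene.terrain_grids()
chm, mix, _ = scene.forest_grids()
inputs = PipelineInputs(dtm_local=local, dtm_regional=regional, chm=chm, mix=mix)
cx, cy = spec.centre
mask = ForestMask(values=np.array([[1]], dtype=np.int16), resolution=10.0,
                  origin=(cx - 5.0, cy + 5.0))
config = ModelConfig(rng_seed=42)
result = run_point(plan_run(mask, config).points[0], inputs, config,
                   [datetime.date(2020, 6, 21)])
for layer in ("terrain", "leaf_off", "leaf_on"):
    pair = result["svf"][layer]
    dbt = result["dbt"][layer][0].values
    print(f"{layer:9s} SVF-planar={pair.svf_planar:.3f} "
          f"SVF-hemi={pair.svf_hemi:.3f} DBT(12:00)={dbt[12]:.3f} "
          f"daily-mean-DBT={dbt.mean():.3f}")
```

prints

```
terrain   SVF-planar=0.763 SVF-hemi=0.515 DBT(12:00)=1.000 daily-mean-DBT=0.400
leaf_off  SVF-planar=0.133 SVF-hemi=0.078 DBT(12:00)=0.632 daily-mean-DBT=0.097
leaf_on   SVF-planar=0.071 SVF-hemi=0.040 DBT(12:00)=0.440 daily-mean-DBT=0.056
```

The terrain layer reproduces the crater's spherical-cap closed forms
(SVF-hemi ≈ 1 − cos 60° = 0.5, SVF-planar ≈ sin²60° = 0.75; the small
offsets are raster discretisation of the rim).  Below the canopy both SVFs
drop sharply, leaf-on below leaf-off — denser summer foliage admits less
light — and at noon the sun reaches the floor through gaps only part of
the hour (DBT 0.44–0.63).  The layer ordering
`leaf_on ≤ leaf_off ≤ terrain` holds per hour by construction, because the
two foliage states share their binarisation draws.

There is also a CLI mirroring the library
(`hemirad fixtures` / `plan` / `run`), e.g.

```sh
hemirad fixtures --terrain crater --forest gapped --out fixture/
hemirad run --mask fixture/mask.tif --dtm-local fixture/dtm_local.tif \
    --dtm-regional fixture/dtm_regional.tif --chm fixture/chm.tif \
    --mixrate fixture/mixrate.tif --days 2020-06-21 --out out/
```

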