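# Methods

## Model overview

`hemirad` estimates potential light availability at points on a landscape
from rasters alone: bare-earth elevation at two resolutions, a canopy
height model (CHM), and an evergreen/deciduous mix-rate map.  The central
intermediate is a *synthetic hemispheric image*: a binary sky/obstructed
field over the upper hemisphere on a regular 1°×1° (zenith × azimuth)
grid, emulating an upward-looking fisheye photograph (rendered south-up,
east-right).  Zenith bins cover [k, k+1)° with centres at k+0.5°; azimuth
is measured clockwise from north with the same convention.  All
downstream quantities — two sky-view factors and a time-resolved
direct-beam transmissivity — are functionals of this image.

### Terrain stage

For each model point the terrain horizon line is the per-azimuth maximum
elevation angle `atan((z − z_viewer)/d)` of the surface, evaluated at 1°
azimuthal increments.  Two passes are combined by elementwise maximum: a
local pass over the high-resolution DTM (default 5 m, 300 m radius)
resolving between-point differences, and a regional pass over the coarse
DTM (default 50 m, 25 km radius) capturing distant ridgelines.  The two
search ranges overlap; because the combination is a maximum, the result
is insensitive to whether the stages overlap or partition.  Rays are
sampled at half-cell intervals with bilinear elevation interpolation —
the sampling scheme is our choice; half-cell spacing keeps aliasing below
the grid's resolving power, and bilinear sampling reproduces planar
surfaces exactly.  Where the local DTM holds no data the local profile is
NaN and the regional profile alone survives the maximum.  The viewer
sits on the interpolated ground surface (viewer height 0 by default,
configurable).  Negative horizon angles are retained in the profile but
floored at zero when thresholding the image: terrain below the
horizontal plane cannot open sky beyond the astronomical horizon.

No earth-curvature or refraction correction is applied over the 25 km
regional radius; at that range the curvature drop (~50 m) is comparable
to one coarse-DTM cell and is a known, documented omission.

### Canopy stage

Within forests the canopy is modelled as the volume between the ground
surface and ground + CHM height — the CHM carries no crown-base
information, so the column is filled; this overestimates path lengths
under high-crowned stands and is the main structural simplification.
For each of the 90×360 directions a ray is marched from the viewer in
0.5 m steps (half the 1 m CHM cell, bounding the path-length error at
about one cell diagonal).  CHM lookups are nearest-neighbour so crowns
keep their crisp 1 m footprints; ground lookups are bilinear.  Marching
stops once the ray clears the highest possible canopy top or its
horizontal footprint leaves both the 300 m local search radius and the
grid — a pure optimisation that cannot change the result.

The ray accumulates the within-canopy path length `l` and the
path-weighted foliage density `Σ λ·l` (several λ maps can be accumulated
in one march, so leaf-on and leaf-off share the geometry work).  The
probability that a thin light beam penetrates is the Beer–Lambert law

    p = exp(−G · Σ λ·l)

with projection function `G = 0.5` (randomly oriented foliage).  The
probability field is binarised into a sky/obstructed canopy image:
independent per-direction Bernoulli draws from a seeded generator
(`sky ⇔ u < p`), so the expected sky fraction per direction equals `p`
and a fixed seed reproduces the image bit for bit.  Because the two leaf
conditions of one point share the same draw field `u`, their images are
nested whenever `λ_on ≥ λ_off`, which makes the leaf_on ≤ leaf_off layer
ordering hold per direction, not just in expectation.  A deterministic
threshold mode (`sky ⇔ p ≥ 0.5`) exists for regression work.  The final
sub-canopy image is the intersection of the canopy and terrain images.

### Foliage density maps

λ (m⁻¹, "effective" in that it also represents woody elements) is mapped
per 1 m canopy pixel by linear interpolation between forest-type
endpoints according to the local evergreen fraction `f` from the 10 m
mix-rate raster (replicated to 1 m by nearest neighbour):
`λ = f·λ_evergreen + (1−f)·λ_deciduous(condition)`.  The deciduous
endpoint depends on the leaf condition and on the larch override: cells
above 1500 m a.s.l. where the ecoregion expects needleleaf forest, the
dominant-leaf-type product says broadleaf, and the mix rate calls the
cell mostly deciduous (`f < 0.5`) are treated as larch (deciduous
needleleaf).  The elevation gate is folded into the rule as a fourth
conjunct; without it, lowland product disagreements would be mislabelled
larch.  Leaf-on larch uses the evergreen λ (similar crown density in
leaf).

**The shipped λ defaults are uncalibrated placeholders** (evergreen 0.75,
deciduous leaf-on 0.6, leaf-off 0.2, larch leaf-off 0.15 m⁻¹).  Proper
values require calibration against hemispherical photographs or
crown-segmented lidar, which is out of scope here; quantitative use must
supply calibrated values through `ModelConfig`.

### Sky-view factors

Both SVFs aggregate the image over 10° zenith rings: within a ring each
1° cell contributes with its solid angle (∝ sin of its zenith centre),
and rings are weighted analytically — `w ∝ sin²θ₂ − sin²θ₁` for the
planar variant (projected annulus area: the view of a flat horizontal
receiver) and `w ∝ cosθ₁ − cosθ₂` for the hemi variant (annulus area on
the hemisphere: a 3-D receiver).  Weights are closed-form rather than
numeric so that images whose obstruction boundaries fall on ring edges
reproduce the spherical-cap identities exactly (uniform 30° horizon:
planar 0.75, hemi 0.5).  The (zenith, azimuth) grid with solid-angle
weights is projection-free; no fisheye projection (equiangular or
equisolid) needs to be chosen.

### Solar track and DBT

Solar positions use the NOAA solar-calculator equation set (Julian
century → declination and equation of time → true solar time → hour
angle → zenith/azimuth).  The test suite carries a second, scalar
implementation written independently from the spreadsheet layout; the
two agree below 0.01°.  Atmospheric refraction is off by default —
the model computes *potential* transmissivity and near-horizon geometry
is dominated by terrain — but is available behind a config flag.
Timestamps are naive civil time at a fixed UTC+1 offset year-round, with
each timestamp marking the start of its averaging period; the hourly
series of the leap year 2020 therefore has exactly 8784 steps.  Each
model point gets its own track (2-minute cadence by default) from its
geographic coordinates, obtained from the projected CRS by the built-in
Swiss LV95 polynomial inverse or a user-registered local anchor.

DBT at one instant is the sky fraction of the image over the solar disc
(apparent diameter 0.53°).  The disc is smaller than a 1° image cell, so
it is supersampled with a fixed 13×13 grid clipped to the disc (129
directions); a nearest-cell lookup would make DBT binary and lose
partial occlusion at the horizon line.  Sub-samples below the
astronomical horizon carry no image pixel and are excluded from the
ratio, making the flat-scene DBT an exact 1/0 step function of the solar
zenith at 90°.  The 2-minute series is averaged to hourly steps by plain
arithmetic mean over the 30 values of each hour.

### Radiation reconstruction

`SWR_i = SWR_dir,i·DBT_i + SWR_dif,i·SVF` combines the two quantities
with above-canopy direct/diffuse forcing; which SVF variant to use is the
caller's modelling choice (planar for flat ground or snow surfaces, hemi
for 3-D receivers).  Partitioning a combined forcing into direct and
diffuse components is out of scope.  With no forcing available, the
ceiling `I₀·cosθ·τ_atm` applies, `I₀ = 1361 W m⁻²`, clamped to zero at
night.  Storing DBT/SVF at 8-bit percent resolution perturbs the
reconstruction by at most 0.5 % of the total forcing.

## Orchestration and file products

The 10 m forest mask (0 = no run, 1 = forest, 2 = open) defines one
model point per non-zero cell centre; code 1 points get the terrain,
leaf-on and leaf-off layers, code 2 points the terrain layer only.  SVF
layers are written as single-band GeoTIFFs and DBT as daily NetCDF files
with (time, y, x) dimensions, both as 8-bit integer percentages.  The
GeoTIFF nodata sentinel is 255; the NetCDF files use −1 because the
classic NetCDF byte type is signed.  GeoTIFF georeferencing travels in
the standard ModelPixelScale / ModelTiepoint / GeoKeyDirectory /
GDAL_NODATA tags; geographic (degree-unit) rasters are rejected at read
time.  Per-point binarisation seeds derive from (global seed, point
index), so tiling, point order and interrupted-then-resumed runs are
bitwise reproducible.

## Synthetic scenes and the oracle

All tests run on parametric scenes: flat and inclined planes, a conical
crater whose rim subtends a chosen angle from the centre, seeded Gaussian
hills; forests as a single cuboid crown, a plantation lattice, a uniform
slab, or seeded random crowns with gaps.  Grids are *samples* of
closed-form surfaces, so the dense ray-marching oracle (0.1 m steps
against the analytic geometry) is independent of raster interpolation
and provides ground truth for horizon angles and canopy path lengths.
Random crown placement is snapped to whole metres so footprints are
exactly representable on the 1 m CHM: the oracle then measures
ray-marching error, not rasterisation aliasing.  What the fixtures do
not emulate: real crown shapes (ellipsoids, conifer cones), vertical
foliage profiles, terrain–canopy correlation, and CHM measurement noise —
passing tests demonstrate geometric correctness of the machinery, not
calibration against real forests.

## Numerical choices and problem sizes

- Horizon rays: half-cell sampling, bilinear; tolerance against the
  oracle is one cell's angular subtense at the horizon-defining distance.
- Canopy rays: 0.5 m steps; tolerance one CHM-cell diagonal (√2 m).
- Disc supersampling: 129 fixed sub-directions; the step-function
  property at the astronomical horizon is exact by construction.
- Ties: a direction exactly at the horizon angle is obstructed
  (`sky ⇔ elevation > horizon`); binarisation uses strict `u < p` so
  `p = 0` never yields sky and `p = 1` always does.
- Percent encoding rounds half-up; decoding divides by 100.
- Test and acceptance runs use desk-scale scenes (≤ 300 m extents,
  ≤ 64×64 local DTMs, single-day DBT tracks), chosen so the whole suite
  completes in about a minute while still exercising every stage;
  national-scale runs differ only in point count.

## Known limitations

- Canopy fills the ground-to-CHM column: no crown-base height, trunks,
  or within-crown density profiles.
- λ defaults are placeholders (see above).
- No earth curvature/refraction over the regional horizon radius.
- Eq. `SWR` uses a single static SVF; seasonal transitions between
  leaf-on and leaf-off layers (green-up, senescence) are left to the
  user, e.g. by blending the two layers with a phenology signal.
- Buildings and other non-terrain obstacles are not modelled.
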