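# Methods

`greenozone` implements a desk-scale version of the computational chain that
links urban greening to ozone health burden: land-cover fusion → PFT/LAI
assignment → biogenic isoprene emissions → paired-scenario MDA8 O₃ analysis →
O₃-attributable mortality. The chemistry–transport step that would normally
connect emissions to ozone (a WRF-CMAQ-class model) is replaced by a
stochastic scenario-field generator with known injected structure, so that
every downstream statistic has a recoverable ground truth. This note records
the models, the defaults and why, the numerical choices, and what the
synthetic design does and does not demonstrate.

## Domain and grids

All rasters live on a regular planar grid with square cells; coordinates are
kilometres from the south-west corner and row 0 is the southernmost row.
Latitude enters only as a nominal domain-centre value (default 31° N) used by
the tree-phenology rule, with northward offsets converted at 111.32 km per
degree. The analysis ("coarse") grid defaults to 1 km cells over a 50 km
domain — the innermost-domain resolution typical of urban air-quality
modelling — and the urban land-cover raster to 10 m cells, the resolution at
which street trees and parks are resolvable. The fine resolution must divide
the coarse resolution exactly; fusion is then simple block bookkeeping with
no resampling error.

## Land cover, PFTs and LAI

Vegetation is described by fractional coverages χ_j of 16 plant functional
types (PFTs: needleleaf/broadleaf × evergreen/deciduous trees, shrubs,
grasses, crops), with Σ_j χ_j ≤ 1 per cell. Outside the urban mask χ comes
from the coarse product; inside it, χ_j is the areal fraction of fine cells
of each vegetation class within the coarse cell. Urban trees are assumed
broadleaf; whether evergreen or deciduous follows latitude, with a
configurable cutoff defaulting to 30° N/S (the conventional
subtropical/temperate divide — so a 23° N city gets evergreen, a 40° N city
deciduous). Shrub, grass and crop map to a single PFT each. The class→PFT
maps are shipped as editable CSVs.

Leaf area index is assigned per cell as LAI = Σ_j χ_j · LAI_ref(j), with a
per-PFT reference table (trees 3.5–5.0, shrubs 1.5–2.0, grasses 1.0–2.5,
crops 3.0–3.5 m² m⁻²; editable CSV). This is deliberately the simplest
empirical PFT→LAI relationship; no seasonal phenology beyond a single 8-day
epoch index is modelled.

Two invariants are enforced and tested: fusion is idempotent, and the
vegetated χ total of an urban cell equals the fine-raster vegetated areal
fraction exactly (no area is created or lost).

## Isoprene emissions

Fluxes follow the MEGAN formulation: F_i = γ_i Σ_j ε_{i,j} χ_j, with the
activity factor γ_i = C_CE · LAI · γ_L · γ_T · γ_LA · γ_SM · γ_CI. The light
and temperature responses use the published MEGAN2.1 closed forms for
light-dependent (isoprene-like) emissions:

* γ_T = E_opt · CT2 · e^{CT1·x} / (CT2 − CT1·(1 − e^{CT2·x})),
  x = (1/T_opt − 1/T)/0.00831, with CT1 = 95, CT2 = 230, T_opt = 313 K,
  E_opt = 2.034. The form is single-peaked with maximum E_opt exactly at
  T_opt (tested); the past-temperature dependence of E_opt and T_opt is not
  modelled — they are fixed, overridable parameters.
* γ_L = C_P · αP/√(1+α²P²) with α = 0.0027, C_P = 1.066; zero in the dark
  and saturating near C_P.

γ_LA, γ_SM and γ_CI default to 1.0 (the synthetic pipeline carries no leaf
age, soil moisture or CO₂ drivers); each is overridable. Leaf temperature is
approximated by 2 m air temperature (no canopy energy-balance model). C_CE
is computed at run time so that γ = 1 at standard conditions (LAI = 5,
T = 303.15 K, PAR = 1500 µmol m⁻² s⁻¹), the MEGAN normalization convention;
with the default responses this gives C_CE ≈ 0.190. Standard emission
factors ε_j (µg m⁻² h⁻¹) ship as a CSV with MEGAN2.1-style isoprene values
(broadleaf trees 7 000–11 000, shrubs 2 000–4 000, grasses 200–1 600, crops
≈ 1); additional species are supported as extra CSV columns. Seasonal
budgets integrate F·area·Δt to Gg and decompose exactly into urban +
non-urban totals.

## MDA8 and scenario analysis

MDA8 O₃ is the daily maximum of 8-hour running means. The window convention
is the common regulatory one (none is universal): 24 windows per day
starting 00:00–23:00 local, each assigned to its start day and allowed to
draw hours from the next day; a window needs ≥ 6 of 8 valid hours and a day
≥ 18 valid windows, otherwise NaN. The implementation is vectorized but is
pinned, value for value, to an exhaustive window-scan oracle in the tests.

A scenario pair holds hourly ozone from a Base run (urban BVOC emissions
excluded) and a UG run (included), sharing grid and time axes; the first 4
days are treated as model spin-up and dropped at load (configurable).
Analysis products: per-day and seasonal-mean ΔMDA8 = UG − Base per cell;
relative change with the Base seasonal mean as denominator; urban vs
suburban boxplot summaries (min/p25/p50/p75/max plus mean); the daily
urban-mean Δ correlated with domain daily-mean temperature (Pearson r,
two-sided t-distribution p; per-cell pooling available behind a flag, since
either choice is defensible); and population-weighted exposure Σ(P·Δ)/Σ(P).

## Health burden

The attributable-mortality chain is the attributable-fraction form used in
grid-level assessments: RR(C) = rr^{(C−C0)/10} above the theoretical
minimum-risk concentration C0 = 32.4 ppb and exactly 1 below it; the
population-weighted mean RR̄ over the domain; the underlying incidence
Î = I/RR̄; and M = Σ_g P_g·Î·(RR(C_g)−1) summed over cells and age groups.
Exposure C_g is the seasonal mean of daily MDA8 per cell (an annual-mean
variant is a parameter away). The default concentration–response is
rr = 1.06 per 10 ppb for COPD — an editable parameter, never baked into
outputs. A seasonal burden scales annual incidence by season_days/365; both
this seasonal mode and the full-year mode are available because burden
studies are not consistent on the point. Attribution runs the chain
independently on the Base and UG exposure surfaces: attributed deaths are
M_UG − M_Base, the attribution fraction (M_UG − M_Base)/M_UG, which lies in
[0,1] whenever UG exposure dominates cellwise. Two useful exact limits are
tested: uniform C collapses the chain to M = ΣP·I·(RR−1)/RR, and raising any
cell's concentration never decreases M.

## The synthetic generator

The generator emulates the statistical structure of the study conditions,
not any real city. One seed drives four independent RNG streams (land
cover, meteorology, scenario, population), so a fixed seed gives
bit-identical outputs.

*Land cover.* A circular urban core (radius 15 km in a 50 km domain) with
clustered vegetation patches from thresholded smoothed Gaussian fields;
the vegetated count inside the mask matches `urban_green_fraction`
(default 0.35, a typical Chinese-megacity greenspace share) to rounding.
The urban vegetation mix is tree-dominated (60/10/25/5 per cent
tree/shrub/grass/crop). Suburban cells carry smoothly varying PFT fractions
whose vegetated total rises from 0.45 at the urban fringe toward 0.90 at the
domain edge, forest-dominated — chosen so that urban areas contribute
roughly 15–25 % of domain isoprene emissions, the regime the analysis is
about (measured ≈ 24 % at the defaults).

*Meteorology.* Hourly 2 m temperature = 27 °C mean + AR(1) daily anomalies
(sd 2.5 °C, lag-1 correlation 0.6) + a 5 °C diurnal cosine peaking at 15:00
+ a 1.5 °C urban-heat-island kernel; the diurnal term has zero daily mean,
so hot days (daily mean > 30 °C) are driven by the anomalies alone, and the
recipe is simple enough to re-simulate independently in a test. PAR is a
clear-sky half-sine (06–18 h, 2 000 µmol m⁻² s⁻¹ max) scaled by a daily
clearness factor correlated with the temperature anomaly; exactly zero at
night.

*Scenario pair.* Base ozone is a diurnal profile (35 ppb nights, ~70 ppb
afternoon peak — seasonal-mean MDA8 near 60–65 ppb, so relative
enhancements land in the few-per-cent range and exposures sit above C0)
plus 1.5 ppb °C⁻¹ temperature sensitivity and additive Gaussian noise
(sd 2 ppb, clipped at 0). The enhancement Δ is separable: a spatial kernel
(Gaussian urban bump advected downwind along a constant wind — default
(2.0, 0.5) km h⁻¹ with a 6 h plume e-folding time; the wind is a single
constant vector per run because no per-city climatology is assumed), a
photochemical diurnal shape peaking at 13:00, a daily temperature modifier
1 + temp_coupling·(T_d − T̄) (default 0.08 °C⁻¹), and mean-one lognormal
noise per cell-hour (σ = 0.15) and per day (σ = 0.10) — multiplicative
lognormal so Δ stays positive. The noise-free amplitude is calibrated by
secant iteration (the urban-mean seasonal ΔMDA8 is piecewise linear in the
amplitude) until it equals `delta_o3_urban_ppb` (default 3.6 ppb) to 1e-9;
because the noise has unit mean, the noisy fields recover it to within
sampling error (~2 % at the default sizes). With the injected difference
set to 0 the two scenarios are identical arrays.

*Population and incidence.* Gaussian radial density (scale 0.75 × urban
radius) over a 1 % floor with smooth lognormal texture, normalized exactly
to 20 million people; ≥ 50 % of them fall inside the urban mask. Incidence
is one aggregate age group at 9×10⁻⁴ COPD deaths person⁻¹ yr⁻¹ (a
China-like all-age rate); multi-group tables are supported throughout the
health module.

*What passing tests show and don't.* The generator reproduces the
qualitative structure the analysis relies on — positive, urban/downwind-
concentrated, temperature-coupled enhancements over a realistic base — and
the pipeline provably recovers what was injected. It does not emulate real
meteorology, chemistry regimes (the VOC-/NOₓ-limited transition), synoptic
transport, or observed land cover; recovery here validates the analysis
chain, not any real-city estimate.

## Numerical and design choices

- Problem sizes: the test and acceptance runs use 50×50 coarse cells with
  26 analysis days (+4 spin-up) and the unit tests 12–30 km domains with
  8–20 days; these sizes make every statistic stable at a few per cent
  while the whole suite runs in seconds.
- Amplitude calibration operates on the noise-free fields; noise is applied
  afterwards and is mean-preserving by construction.
- Degenerate inputs: relative change is NaN (flagged, excluded) where the
  Base seasonal mean is 0; correlations on constant series return NaN
  rather than warn; empty urban or suburban strata, zero total population,
  mismatched grids or time axes, negative incidence and out-of-range
  temperatures all raise.
- Tie-breaks: MDA8 ties across windows resolve to the same maximum value
  regardless of which window attains it, so no convention is needed.
- I/O: rasters are plain TIFF with a JSON sidecar carrying the grid
  geometry; gridded time series are NetCDF3 (xarray, scipy backend) with a
  CF-style time axis; tables are CSV. The pipeline manifest records the
  config hash, seed, package version and SHA-256 of every artifact, and a
  rerun with the same config is byte-identical.

## Known limitations

Planar geometry (no CRS/projection handling); a single constant wind per
run; fixed E_opt/T_opt (no past-temperature memory in the temperature
response); no canopy radiative transfer or leaf energy balance; isoprene
only by default (other species enter only through extra ε columns); one
aggregate age group in the default synthetic inputs; no uncertainty
propagation on incidence or concentration–response parameters.
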