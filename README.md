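# greenozone

Urban greening cools streets and stores carbon, but trees also emit biogenic
volatile organic compounds (BVOCs, chiefly isoprene) that form ozone in the
NOₓ-rich, VOC-limited air of city cores. `greenozone` is a Python package
for quantifying that trade-off end to end: it fuses fine urban land cover
into a plant-functional-type (PFT) map, computes MEGAN-form isoprene
emissions, analyses paired ozone scenarios with and without urban BVOC
emissions, and converts the exposure difference into ozone-attributable
mortality. It is written for air-quality and environmental-health
researchers who want a tested, reproducible implementation of this chain;
a built-in synthetic generator with known injected structure stands in for
chemical-transport-model output, so the whole pipeline runs self-contained.

## The models

**Emissions.** Per cell and hour, the flux of species *i* is

    F_i = γ_i · Σ_j ε_{i,j} χ_j,     γ_i = C_CE · LAI · γ_L · γ_T · γ_LA · γ_SM · γ_CI

with χ_j the fractional coverage of each of 16 PFTs, ε_{i,j} standard
emission factors, and γ the activity factor composed of the MEGAN2.1 light
and temperature responses (γ_T single-peaked at T_opt, γ_L saturating in
PAR), normalized so γ = 1 at standard conditions. In urban areas χ comes
from a 10 m land-cover layer (trees assumed broadleaf, evergreen or
deciduous by latitude); elsewhere from the coarse PFT product.

**Exposure.** MDA8 O₃ — the daily maximum of all valid 8-hour running
means — is computed per cell for a Base scenario (no urban BVOC emissions)
and a UG scenario (with them); ΔMDA8 = UG − Base isolates the
urban-greening effect, analysed by urban/suburban stratum, against
daily-mean temperature (Pearson r), and as population-weighted exposure.

**Health.** Attributable deaths follow the attributable-fraction form

    M = Σ_g P_g · Î · (RR(C_g) − 1),   Î = I / RR̄,   RR(C) = rr^((C−C0)/10) for C > C0

with C0 = 32.4 ppb and rr = 1.06 per 10 ppb (COPD, editable). Running the
chain on both exposure surfaces splits the burden into a Base part and an
urban-greening part, (M_UG − M_Base)/M_UG.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```sh
greenozone run-all --config examples/demo_config.yaml
```

generates a 30 km synthetic megacity domain (20 analysis days + 4 spin-up,
3.6 ppb injected urban ΔMDA8), runs all five stages into
`scratch/demo_run/`, and prints:

```json
{
 "emissions": {
  "total_Gg": 0.2740960198391408,
  "urban_Gg": 0.06327226100215455,
  "urban_fraction": 0.23083976571161907
 },
 "ozone": {
  "urban_mean_delta_mda8_ppb": 3.6227557336049663,
  "suburban_mean_delta_mda8_ppb": 1.021905257484054,
  "relative_change_pct": 5.675750921578454,
  "pearson_r": 0.9414602835220091,
  "pop_weighted_delta_ppb": 2.6692767731519575,
  "simple_mean_delta_ppb": 1.7617027262473357
 },
 "health": {
  "m_base": 162.99090296745402,
  "m_ug": 175.77949888243825,
  "attributed": 12.788595914984228,
  "fraction": 0.07275362597055343
 }
}
```

Reading it: urban vegetation supplies ~23 % of the domain's seasonal
isoprene (0.063 of 0.274 Gg); the recovered urban-mean MDA8 enhancement,
3.62 ppb (a 5.7 % relative increase), matches the 3.6 ppb the generator
injected and is three times the suburban value; the population-weighted
enhancement (2.67 ppb) exceeds the simple spatial mean (1.76 ppb) because
both people and the ozone increment concentrate in the core; and of the
~176 ozone-attributable COPD deaths in the 20-day window, ~13 (7.3 %) are
attributable to urban-greening BVOC emissions.

The same pipeline is available as a library (`greenozone.run_all`, or the
stage functions `generate_*`, `fuse_landcover`, `emission_flux`, `mda8`,
`delta_mda8`, `attributable_mortality`, …) and as per-stage CLI subcommands
(`generate`, `landcover`, `emissions`, `ozone`, `health`).

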