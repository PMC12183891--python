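# vipertherm

Mechanistic modelling of climate-driven activity restriction in grassland
vipers (and, with other trait tables, any small terrestrial ectotherm).

Cool-adapted grassland vipers of Eurasia are squeezed by warming: as
environmental temperatures rise above a population's voluntary thermal
maximum (VTmax), the hours in which a snake can be active at the surface
shrink. `vipertherm` quantifies that squeeze the way mechanistic niche
modellers do — from physics and physiology rather than from correlative
range maps:

1. **Microclimate.** For each occurrence grid cell, twelve monthly mean air
   temperatures and diurnal ranges are expanded into a full 24 × 365 hour
   year of air temperature, clear-sky solar irradiance, sky and substrate
   temperature, and wind. Future climates enter through additive monthly
   "warm" offsets (delta-method downscaling: offset = fine/future monthly
   mean − baseline monthly mean).
2. **Operative temperature.** The animal is a non-thermoregulating cylinder
   (mass *m*, length:diameter *k*, solar absorptance *a*, longwave
   emissivity *ε*). Its operative temperature *T*e each hour is the unique
   root of the steady-state energy balance

   *a S A*sil + *ε σ* (*A*lat/2)(*T*sky⁴ + *T*sub⁴) = *ε σ A*lat *T*e⁴ + *h A*lat (*T*e − *T*a),

   with the convection coefficient *h* from a cylinder-in-crossflow
   Nusselt–Reynolds correlation. The root is found by vectorized bisection
   to an energy residual below 10⁻⁶ W.
3. **Restriction hours.** *h*r is the number of hours in the year with
   *T*e > VTmax — time unavailable for foraging, mating, or dispersal.
4. **Scenario statistics.** Per-taxon medians with 5th/95th percentile
   intervals, Mann–Whitney rank-sum comparisons of current vs. future *h*r
   (exact by enumeration for small samples), Δ*h*r = future − current, and
   an ordinary least-squares model of site-level Δ*h*r on latitude and
   elevation — all implemented from first principles.

A synthetic-data generator produces sites, taxon traits, and current plus
3 GCM × 2 SSP future climates over a realistic latitudinal/elevational
envelope with *known* warming gradients, so the entire pipeline is testable
against ground truth without any climate-data downloads.

## Worked example

```sh
vipertherm synth --out demo/inputs --n-sites 20 --n-taxa 3
vipertherm run \
  --sites demo/inputs/sites.csv --traits demo/inputs/traits.csv \
  --climate demo/inputs/climate.csv --out demo/out \
  --scenarios "current,gcm1_ssp126,gcm2_ssp126,gcm3_ssp126,gcm1_ssp585,gcm2_ssp585,gcm3_ssp585"
```

`demo/out/manifest.json` then carries the headline numbers of this run:

```json
{
 "median_hr_current": 320.0,
 "median_hr_ssp126": 774.0,
 "median_hr_ssp585": 1130.5,
 "percent_increase_ssp126": 141.875,
 "percent_increase_ssp585": 253.28125
}
```

Across the 20 synthetic sites, the cross-taxa median restriction time rises
from 320 h per year under the current climate to 774 h (pooled low-emission
scenarios) and 1130.5 h (pooled high-emission scenarios) — increases of
roughly 142% and 253%. `regression.csv` shows where the losses fall:

```
   ssp      term     beta       se        t        p
ssp126  latitude 7.775607 2.678232 2.903261 0.009894
ssp126 elevation 0.078049 0.023013 3.391537 0.003471
ssp585  latitude 8.460538 2.736073 3.092219 0.006614
ssp585 elevation 0.051004 0.023510 2.169463 0.044514
```

Both betas are positive and significant: each degree of latitude adds ~8 h
of extra restriction and each metre of elevation ~0.05–0.08 h, i.e.
high-elevation and northern populations lose the most activity time — the
spatial fingerprint of elevation- and latitude-amplified warming acting on
locally adapted thermal tolerances. `summary.csv`, `tests.csv` and
`comparisons.csv` hold the per-taxon percentile summaries, rank-sum tests
and per-site scenario deltas.

The same analyses are available in memory via
`vipertherm.run_analysis(sites, traits, scenarios)`; the file-based
pipeline is `vipertherm.run_pipeline(RunConfig(...))`.

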