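# reefcast

Projection of coral-reef habitat persistence from carbonate budgets.

For a reef framework to persist, calcium-carbonate production by corals and
crustose coralline algae (CCA) must outpace loss to bioerosion and
dissolution. `reefcast` takes monthly climate forcing — sea-surface
temperature (SST) and aragonite saturation state (Ω_Ar) — together with a
ReefBudget-style benthic census, and projects per-transect annual carbonate
budgets, vertical reef accretion potential, and accumulated reef height to
2100 across a matrix of emission scenarios, coral thermal-adaptation levels,
and restoration planting schedules. It is aimed at reef ecologists and
managers who need site-specific forecasts of when a reef tips from net
accretion to net erosion and whether its vertical growth can keep pace with
sea-level rise (SLR).

## Model core

Each year, for each transect:

1. **Thermal stress.** Monthly hotspots `max(0, SST − (T_b + a))` above the
   local bleaching threshold `T_b` (default 31.3 °C) raised by the
   adaptation offset `a` are summed over every rolling 3-month window and
   converted to degree heating weeks (DHW) by × 4.35 weeks/month. The
   year's maximum DHW classifies bleaching: severe at ≥ 8 DHW, modest at
   4–8 DHW. The onset of annual severe bleaching (ASB) is the first year
   from which every remaining year is severe.
2. **Community dynamics.** Coral cover grows 1 %/yr (0.5 % in bleaching
   years), scheduled restoration cover is planted, then bleaching mortality
   removes a species-specific fraction of cover (modest bleaching causes
   one third of the severe impact). Dead cover becomes substrate available
   to microborers.
3. **Carbonate budget.** Net community calcification (NCC, kg CaCO₃ m⁻²
   yr⁻¹) = coral + CCA production − parrotfish − urchin − sponge −
   microborer erosion − sediment dissolution, with production and
   chemically mediated erosion modulated by additive linear SST/Ω_Ar
   response curves (grazing is environment-independent).
4. **Accretion.** Maximum reef accretion potential
   `RAP_max = (NCC + sediment infill) / (ρ (1 − porosity))` in mm yr⁻¹,
   with ρ = 2.89 g cm⁻³, porosity 30 %, and infill crediting 25 % of
   parrotfish and 50 % of other macro-bioeroder sediment. Accumulated
   height is the running sum of RAP_max; keeping pace with SLR is judged on
   cumulative height versus cumulative rise.

## Worked example

```python
from reefcast import RateConfig, run_projection, mean_trajectory, onset_of_net_erosion
from reefcast.synthetic_data import gen_scenario_pair
from reefcast.thermal_stress import annual_max_dhw, asb_onset_year, classify_years

pair = gen_scenario_pair(seed=1)          # harsh vs mild forcing, shared reef
rates = RateConfig()
for spec in (pair.harsh, pair.mild):
    trajs = run_projection(pair.transects, spec, rates)
    years, mean_ncc, sd = mean_trajectory(trajs)
    asb = asb_onset_year(classify_years(
        annual_max_dhw(spec.climate, spec.thermal), spec.thermal))
    print(spec.label, "ASB onset:", asb,
          "erosion onset:", onset_of_net_erosion(years, mean_ncc),
          "NCC 2019: %.2f" % mean_ncc[0], "NCC 2100: %.2f" % mean_ncc[-1])
```

prints

```
SSP5-8.5-like ASB onset: 2055 erosion onset: 2060 NCC 2019: 2.49 NCC 2100: -2.17
SSP2-4.5-like ASB onset: 2083 erosion onset: 2088 NCC 2019: 2.49 NCC 2100: -1.11
```

The six synthetic transects start near 25 % coral cover and a healthy
budget of ~2.5 kg CaCO₃ m⁻² yr⁻¹. Under the harsh (high-emission-like)
forcing, annual severe bleaching sets in mid-century and the mean budget
turns persistently negative (net framework erosion) five years later;
milder forcing delays both by roughly three decades. Raising the bleaching
threshold (thermal adaptation) or adding restoration planting delays — but
does not prevent — the transition while severe bleaching eventually becomes
annual.

The same experiment matrix is available from the shell:

```sh
reefcast simulate --seed 1 --out results/      # full scenario matrix
reefcast synth climate --seed 1 --out climate.csv
reefcast summarize results/
```

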