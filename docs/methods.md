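# Methods

## Model overview

`reefcast` is an annual-time-step, per-transect simulation of reef
carbonate budgets under climate forcing. The state is a benthic census
(percent cover by coral taxon, CCA, sand, available substrate; rugosity;
bioeroder censuses). Forcing is monthly SST and Ω_Ar; monthly resolution is
the native step for forcing because thermal stress is windowed over three
consecutive months, while all biology and budgeting run annually on the
calendar-year means of the 12 monthly values.

The annual update order is fixed and pinned by tests: baseline growth →
restoration planting → bleaching mortality → flux computation. Mortality
runs last so that grown and freshly planted cover faces its planting-year
bleaching; this is the conservative choice among the orderings the
processes admit, and the pinned order makes the convention auditable.
The engine contains no randomness: identical inputs give bit-identical
trajectories.

## Thermal stress and bleaching

Hotspots are positive monthly anomalies above the bleaching threshold
(default 31.3 °C, a locally observed value for an inshore Florida-Keys
patch reef). Degree heating weeks accumulate hotspots over rolling
3-consecutive-month windows (× 4.35 weeks/month); windows may span year
boundaries and are assigned to the year in which they end — the standard
DHW convention, chosen over fixed quarters. Severity bounds are 8 DHW
(severe) and 4 DHW (modest), with boundary values classified into the more
severe class so that the 8-DHW onset line itself counts as severe.

Thermal adaptation is a non-negative offset added to the threshold *inside*
the hotspot computation (not subtracted from DHW afterwards); the standard
offsets explored are 0, 0.25, 0.5, 1 and 2 °C. ASB onset requires severity
to persist to the end of the series: a single severe year is not an
"annual" condition.

Model SST can be anchored to in-situ observations by `bias_correct_sst`,
which shifts the whole series so a reference-month climatology matches the
observed one. The reference window is configurable and defaults to the
August means of 2015–2021.

## Community dynamics

Growth and mortality are both multiplicative on existing cover, so cover is
strictly positive forever: after sustained annual bleaching the
calcification term becomes negligible and bioerosion dictates the budget,
without cover ever reaching exactly zero. Severe-bleaching loss rates for
the eight locally dominant species are field-derived; modest bleaching is
one third of the severe impact, with the derived rates rounded half-up to
one decimal place (this rounding reproduces the published modest-bleaching
column exactly). Taxa without a tabulated rate default to the
cover-weighted mean loss of tabulated taxa present on the transect;
configurable to a hard error instead.

Cover killed by bleaching transfers to available substrate, feeding
microborer erosion; restoration planting draws substrate down first, then
sand, keeping the benthic budget closed at ≤ 100 %. Restoration targets
default to two 10-year phases (2.80 % absolute cover over 2022–2031,
6.20 % over 2032–2041, 9 % combined) split per group; named groups map
50/50 onto their constituent species (*Orbicella faveolata*/*O. annularis*;
*Diploria labyrinthiformis*/*Colpophyllia natans*; *Siderastrea
siderea*/*Porites astreoides*) because the targets name groups, not splits.
Planted cover is added before that year's mortality step, so restored
corals are exposed to bleaching in their planting year.

## Rates and response curves

Base rates follow census-method (ReefBudget-style) arithmetic and apply at
a reference environment (defaults: 26.5 °C annual-mean SST, Ω_Ar 3.9).
Cover-based fluxes (coral, CCA, microborer) are rugosity-scaled because
covers are recorded along the reef contour; parrotfish and urchin belts are
planar and are not. Locally measured calcification rates are used for
*O. faveolata* (12.0), *P. astreoides* (6.9), *S. siderea* (9.9) and CCA
(0.5 kg CaCO₃ m⁻² yr⁻¹); remaining coral, sponge, parrotfish and urchin
rates are editable package defaults of census-method magnitude, shipped as
CSV (`src/reefcast/data/`) with a source column — they are placeholders of
realistic scale, not site measurements, and real applications should
substitute survey-calibrated tables. Microborer erosion uses the
literature-scale 0.240 kg m⁻² yr⁻¹ on available substrate. Urchin rates
are allometric in test diameter (a·d^b per individual).

Environmental modification is an additive linear response,
`max(floor, 1 + a·ΔT + b·ΔΩ)`, exactly 1 at the reference environment;
temperature and Ω contributions add rather than multiply (a deliberately
non-synergistic, conservative interaction). The curve interface is
pluggable; the shipped defaults are calibrated only to reproduce the
*direction* of late-century contribution changes — coral calcification
down, macro- and microborer erosion up, grazing flat, CCA collapse —
under harsh forcing, and make no magnitude claims. CCA carries both a
strong Ω sensitivity and a hard collapse threshold (Ω_Ar 2.0) below which
its production is zero. Sediment dissolution is linear in Ω_Ar decline
below the reference, scaled by sand cover, with a configurable slope
(default 0.10 kg m⁻² yr⁻¹ per unit Ω) and zero baseline.

## Accretion and sea-level rise

RAP_max converts the mass budget to vertical potential through the
effective framework density ρ(1 − porosity) with ρ = 2.89 g cm⁻³ and
porosity 30 % (massive-coral assemblages): 1 kg m⁻² yr⁻¹ ⇒ 0.1/(2.89 × 0.7)
cm yr⁻¹. "Net production" entering RAP_max is NCC itself, so erosion is not
double-counted against sediment infill and negative budgets translate
directly into framework loss. Infill credits 25 % of parrotfish sediment
and 50 % of urchin + sponge sediment back to the framework; microborer loss
is treated as fine-scale/chemical and yields no reincorporable sediment
(the fraction is configurable). Accumulated height is the full running
cumulative sum of RAP_max with the simulation-start reef height as datum.

SLR is linear in time at a configurable cm/decade rate (defaults 3.1 and
4.4, spanning high- and low-resolution earth-system-model estimates for the
region; 3.1 cm/decade integrates to ~25 cm over 2019–2100). Keeping pace is
a cumulative-stock comparison — accumulated accretion versus cumulative
rise, both measured at year end — so a reef that banked height can briefly
tolerate rise rates above its accretion rate. Note that with *linear* SLR
the full per-year rate applies from the first year, so a reef accreting
below ~3 mm yr⁻¹ never keeps pace under the default rates; curved SLR
series (slow early-century rise) can be supplied as CSV to recover an
early keep-pace window. Both the cumulative diagnostic (primary) and the
per-year rate comparison are available in the output tables.

## Synthetic data

The generator emulates the structure, not the values, of the real inputs:
SST = base (26.5 °C) + seasonal sinusoid peaking in August (amplitude
4.5 °C, so unadapted Augusts sit just below the 31.3 °C threshold) +
secular warming + iid monthly noise (sd 0.3 °C); Ω_Ar declines linearly
with small noise. Default end-of-century targets are +3.5 °C / Ω 2.6
(high-emission-like) and +1.8 °C / Ω 3.2 (moderate-mitigation-like). The
scenario pair shares one noise seed and uses a linear trend for both
members, so the mild series is month-by-month no harsher than the harsh
one and scenario-ordering properties hold structurally; a saturating
("stabilizing") trend shape is available separately. Transects draw total
coral cover around 25 % (sd 5 %), *O. faveolata*-dominated, rugosity
1.4–2.1, with sponge, urchin and parrotfish censuses of realistic
magnitude. All randomness descends from one integer seed through spawned
generators.

What passing tests on synthetic data do show: internal consistency, unit
correctness, determinism, and the qualitative response structure
(adaptation and mitigation delay ASB and budget collapse; restoration
raises production; bleaching drives the decline). What they do not show:
calibrated onset years, NCC magnitudes, or keep-pace horizons for any real
reef — those require ensemble climate forcing, measured censuses, and
fitted response curves.

## Numerical choices and degenerate inputs

- Cover budget tolerance 1e-9 percentage points; growth clamps coral cover
  proportionally if the benthos would exceed 100 %.
- Restoration that cannot be absorbed (benthos full) is truncated with a
  logged warning rather than raised, since schedules are exogenous plans.
- `mean_trajectory` uses the sample standard deviation (n − 1); a single
  transect reports sd 0.
- Onset detections (ASB, net erosion) scan from the series end and require
  persistence; an all-clear series returns "absent" (`None`) rather than a
  sentinel year.
- Empty series, negative rates, rugosity < 1, non-positive urchin
  diameters, Ω_Ar outside (0, 6) and SST outside (−2, 45) °C are rejected
  at construction.

## Problem sizes

Default projections run 6 transects × 82 years × 20 matrix cells in under
a second on one core, so the shipped experiment sizes are the full study
conditions, not reductions.

## Known limitations

Storms, disease and water-quality effects are outside the model's scope, as
is carbonate-system solving (Ω_Ar is consumed directly; a user-supplied
solver can be applied upstream). Adaptation is a fixed threshold offset
applied equally to all species from time zero, not a gradual or
species-specific process. Response-curve defaults are directional
placeholders. SLR is linear; mesoscale ocean dynamics are not represented.
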