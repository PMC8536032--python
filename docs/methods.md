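# Methods

## Model structure and integration

The model is a deterministic stock-and-flow system integrated by explicit
Euler stepping with a time step of one month over 2000–2050 (600 steps;
ecosystem-service unit values are stated per hectare per *month*, which is
why a monthly step is the natural resolution). Annual rates are converted
to monthly flows by division by 12, not by compound conversion; with purely
proportional flows this makes the monthly trajectory an exact geometric
sequence, which the test suite uses as a closed-form oracle.

Seven stocks are integrated: population, an air-pollution stock (t CO₂e,
all airborne species aggregated), a waste-pollution stock (t), and four
land-surface stocks (ecosystems, green/blue infrastructure, impervious,
free) whose sum is conserved and checked at every step to 1e-9 relative.
Two bookkeeping cells ride along outside the conservation group: the
cumulative restored area (drives the erosion-prevention effect) and the
previous year's adjusted GDP (refreshed every January; investment budgets
are funded from it, which breaks the simultaneity between GDP and the
investments it finances).

Auxiliaries (pollution index, nature availability, sedentary share,
employment, morbidity, service values, adjusted GDP, budgets, indicator
indices) are pure functions of the stocks at the current step — there is no
intra-step feedback, which resolves the simultaneity the graphical
stock-flow notation leaves ambiguous.

**Negative-stock handling.** Any outflow set that would drive its source
stock negative is scaled down proportionally so the stock lands exactly at
zero; because a clamped outflow is another stock's inflow, the scaling is
iterated to a (monotone, convergent) fixed point. Clamped flows are
reduced, never redirected, so clamping can never create mass.

## Couplings and functional forms

The qualitative dependencies between the subsystems are documented in the
underlying study only at the level of its diagrams, so each coupling is
realised here as the simplest form consistent with every stated dependency,
each in an isolated, swappable function:

- *Nature availability* ν ∈ [0, 1]: the combined ecosystem + GI area
  relative to its year-2000 value, mapped linearly so that total loss → 0,
  the initial state → 0.5 and a doubling → 1. The same half-index mapping
  is used for the service indices entering the expenditure indicator.
- *Sedentary share*: 0.44 × (1 − 0.5 ν): 44% with no natural space,
  linearly reducible by up to half.
- *Morbidity*: additive channels. Sedentary channel = base hospital
  incidence (0.10/yr) × diagnosis share (0.20) × sedentary share relative
  to its no-nature baseline; pollution channel = 0.001/yr per unit of the
  pollution index. Deaths = 0.0096/yr × (1 + 1.5 × morbidity) × P / 12.
- *Pollution index*: air and waste stocks each normalised by their
  year-2000 values and summed with unit weights (equals 2 initially).
- *Employment*: base 0.62, reduced linearly by the relative excess of the
  sedentary share over its year-2000 reference (sensitivity 0.5), lifted
  multiplicatively by the employment-policy lever. Poverty rate = 0.5 ×
  (1 − employment); out-migration = 0.004/yr × poverty × P.
- *Degradation* (ecosystems → free): 0.0006/yr × pollution index ×
  effective erodible share × area / 12. The erodible share starts at
  91.91% and falls proportionally to the cumulative restored fraction of
  the initial ecosystem area (the erosion-prevention effect of restoration
  and conservation).
- *Sealing* (free → impervious): 0.2/yr × (P / P₀) × uncommitted free
  area / 12. Land committed to the month's restoration demand is treated
  as unavailable for development — a deliberate design choice: without this
  priority, budget-driven restoration and sealing would share the single
  small free-surface donor proportionally forever and no investment level
  could stabilise the ecosystem stock.
- *Restoration* (free → ecosystems): monthly budget / EUR 2.0M per ha
  (urban-fringe land acquisition plus restoration works), capped at the
  available free surface.
- *GI build-out* (impervious → GI, then free → GI): monthly budget /
  EUR 0.3M per ha (de-sealing and greening of already-public land, no
  acquisition), drawing on impervious surface first down to a de-sealing
  floor of half the initial impervious area, then on uncommitted free
  surface; total GI is capped at a planning target of 2,500 ha. All three
  caps are configuration knobs.
- *Adjusted GDP*: GDP per capita × population + annual ecosystem services.
  GDP per capita = EUR 15,717.44 × (employment / base employment)^1.
  Household expenditure (housing EUR 3,829.54 + food EUR 1,785.44 per
  person-year, with 10% of housing varying inversely with the regulating
  services and food savings capped at 20%) is reported as an indicator and
  *not* subtracted from adjusted GDP — the services are already counted
  once in the welfare equation, and subtracting the savings again would
  double-count them.
- *Noise and heat-island indices*: normalised multiplicative indicators
  (vehicles × green-barrier factor; impervious share × heat-regulation
  factor), both equal to 1 at the start of the run. They are indicator
  constructions anchored to the stated qualitative dependencies, not
  physical models.

## Scenarios

Scenario 0: all levers off. Scenario 1: 1% of lagged adjusted GDP per year
to ecosystem restoration and 1% to green/blue infrastructure. Scenario 2:
the same investment plus constant policy levers over the whole horizon:
55% per-capita emission cut, 100% waste treatment (no dumping), +10%
employment rate, −25% vehicle fleet, −36% per-vehicle emissions. The
underlying study describes the investment both as "1% + 1%" and as a total
matching 1% of GDP in its result tables; the presets implement the 1% + 1%
reading, and the desk-scale assessment works directly off the reported
tables so its results do not depend on the choice.

## Parameters

Constants printed by the source statistics are used as-is: 535.1
kg/person/yr waste, 80% treatment, 44% sedentary share, 20% diagnosis
share, 91.91% erodible share, EUR 15,717.44 GDP per capita, EUR 3,829.54
and EUR 1,785.44 expenditures, and the CORINE land-cover shares (85.65%
water, 10.8% agricultural, 3.05% artificialized, 0.41% natural, 0.09%
urban green), from which the four initial land shares over the 14.35%
dynamic (non-water) area are derived.

Quantities the sources do not pin down are package defaults, chosen once
for realism at the scale of a ~170,000-inhabitant coastal municipality:
initial population 172,000; study-area dynamic land 22,000 ha (absolute
scale affects only absolute EUR and hectare values, never shares, ratios
or orderings); initial air stock 2.0 Mt CO₂e and waste stock 50 kt
(normalisation constants of the pollution index); emissions 2.5
t/person/yr plus 2.0 t/vehicle/yr at 0.5 vehicles/person; absorption 20
t/ha/yr (upper-range sequestration for a mixed forest/wetland/estuary
system — large enough that the Scenario-2 emission cuts turn the air
balance negative, the behaviour the study reports for its policy
scenario); waste decay 0 (conservative: dumped waste persists);
morbidity-death coefficient 1.5 and migration coefficient 0.004/yr (free
calibration parameters of the demographic core).

## Synthetic data and calibration

The synthetic generators emulate the statistical shape of the calibration
sources: an annual population series 2000–2039 (geometric skeleton at the
default net rate of −0.24%/yr, hence a decreasing trend by construction)
split into an observed window (2000–2020) and a projection window
(2021–2039); an emissions account split into per-capita and per-vehicle
parts; the land-cover share table; and the valuation fixture. Noise is
multiplicative lognormal with mean 1 (positive series, roughly
proportional errors), default coefficient of variation 1%, fully seeded.

Calibration fits the birth and death rates by minimising the sum of
squared *relative* errors (scale-free) between the demographic kernel and
the observed series, with bounded L-BFGS-B from five fixed starting points
(deterministic). A population series alone identifies only the net rate;
when the observed table carries annual birth/death counts — as the real
calibration sources do — the objective uses them and the two rates become
separately identifiable. Validation compares a full default run against
the projection series and passes when every yearly absolute percentage
error is below 10%; under the shipped defaults the worst yearly error is
about 5–6%, the gap coming from the morbidity and migration channels that
the full model adds on top of the pure vital-rates skeleton.

The generators reproduce the *structure* the analysis assumes — trend,
positivity, proportional noise, the two-term emissions split — not the
serial correlation, age structure, economic cycles or measurement
revisions of the real series. Passing tests therefore demonstrate internal
consistency and recoverability under the stated assumptions, not fidelity
to the real Santander data.

## Ecosystem-service valuation

The availability matrix (which of the ten services each of the nine land
classes provides) follows the study's tables. The per-hectare-per-month
unit values are **synthetic placeholders** (the benefit-transfer database
values used in the original work are not reproduced here); they are
order-of-magnitude plausible, shipped as an editable CSV fixture, and
every conclusion the package draws from the valuation is ratio-, ordering-
or invariance-based, so it does not depend on the placeholder magnitudes.
No discounting is applied to service values over the horizon.

## Assessment conventions

Percentage increases and benefit ratios are rounded half-up to two
decimals, matching the presentation of the reported tables. The pairwise
increases satisfy the compounding identity
(1 + r01)(1 + r12) = (1 + r02), asserted to 0.01 points whenever a report
is built. The benefit ratio divides total adjusted GDP by investment —
the reading the reported tables support (their GDP column is 100× their
investment column).

## Known limitations

- Functional forms of the couplings are the package's own minimal
  realisations of qualitative dependencies; absolute trajectories are
  therefore not comparable to the original figures, only orderings,
  ratios, shares and the desk-scale table arithmetic are.
- Single aggregated CO₂e stock; no species-resolved chemistry/transport.
- Static subtype shares within the ecosystem and GI aggregates.
- No age structure, spatial resolution, discounting, or uncertainty bands.
- The absorption functional form is linear per hectare (a saturating form
  would change high-greenery behaviour).
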