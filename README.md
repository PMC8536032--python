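# urbansd — a system-dynamics model of Santander and its bay

`urbansd` simulates the coupled evolution of an urban coastal system — the
city of Santander and the surroundings of its bay — as a stock-and-flow
(system-dynamics) model, and evaluates the economic and quality-of-life
consequences of investing in ecosystem restoration and green/blue
infrastructure. It is written for environmental economists, urban planners
and modellers who want a transparent, scriptable and fully tested
realisation of this kind of eco-socio-economic simulator, including the
synthetic calibration fixtures needed to exercise the whole pipeline
without access to the original regional statistics.

## The model

Five subsystems are coupled through explicit monthly Euler stepping over
2000–2050 (600 steps):

- **Population** `P` — births and deaths with the death rate inflated by the
  morbidity rate; morbidity is the sum of a *sedentary-lifestyle* disease
  channel (44% of the population is sedentary with no natural space, a
  figure that greater availability of ecosystems and green infrastructure
  can reduce by up to half; 20% of hospital diagnoses are tied to
  sedentarism) and a *pollution* channel proportional to the pollution
  index; net out-migration is proportional to the risk-of-poverty rate,
  which moves inversely with employment.
- **Pollution** — a CO₂e air stock fed by per-capita and per-vehicle
  emissions and drained by ecosystem absorption; a waste stock fed by the
  untreated share of 535.1 kg/person/yr of waste (80% treated at baseline).
- **Land surface** — four interconverting stocks (ecosystems, green/blue
  infrastructure, impervious, free surface) whose total is conserved;
  degradation scales with pollution and the erodible share (91.91%),
  sealing with population, restoration and GI build-out with investment.
- **Ecosystem services** — a (land class × service) availability matrix over
  five ecosystem and four GI subtypes, valued per hectare per month.
- **Economy** — the welfare indicator

  `GDP_adjusted = GDP_per_capita × P + ES_annual`

  with GDP per capita tied to the employment rate (EUR 15,717.44/person/yr
  at base), household-expenditure savings tracked as an indicator, and
  investment budgets drawn as fractions of the lagged adjusted GDP.

Three preset scenarios are compared: **0** business-as-usual (zero
investment), **1** investing 1% + 1% of adjusted GDP in ecosystem
restoration and green/blue infrastructure, **2** the same investment plus a
policy package (−55% emissions, 100% waste treatment, +10% employment,
−25% vehicles, −36% vehicle emissions).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import urbansd
from urbansd.assessment import build_report

runs = {n: urbansd.simulate(scenario=n) for n in (0, 1, 2)}
tables = build_report(runs)
print(tables["table5"].to_string(index=False))
```

prints the pairwise adjusted-GDP increases (percent) between the scenarios
at decade years:

```
 year  case0_case1  case0_case2  case1_case2
 2010         1.12        11.59        10.36
 2020         2.26        14.05        11.54
 2030         3.12        16.41        12.89
 2040         3.41        18.82        14.90
 2050         3.72        21.65        17.29
```

Investment and policies always pay: every pairwise increase is positive and
grows toward 2050, and the columns satisfy the compounding identity
`(1 + r01)(1 + r12) = 1 + r02`. The absolute magnitudes depend on the
synthetic valuation fixture and the configured study-area size; orderings,
ratios and percentages are the meaningful outputs.

The same operations applied to the *reported* decade-year tables of the
Santander study reproduce its published arithmetic:

```python
from urbansd.assessment import reference_assessment
print(reference_assessment())
```

```
{'case1_case2_2010_pct': 1.38, 'case1_case2_2050_pct': 16.6,
 'case0_case2_2040_pct': 21.99, 'case0_case2_2050_pct': 32.04,
 'benefit_ratio_2010': 100.0, 'benefit_ratio_2050': 100.01}
```

i.e. the Scenario 1→2 gain is 1.38% in 2010 and 16.60% in 2050, the
compounded Scenario 0→2 gain reaches 32.04% by 2050, and each EUR of
investment coincides with EUR 100 of adjusted GDP.

There is also a command-line interface:

```
urbansd synth --seed 1 --out fixtures/        # synthetic input fixtures
urbansd run --scenario 2 --out traj2.csv      # one scenario trajectory
urbansd calibrate --observed fixtures/population_observed.csv --out fit.json
urbansd assess traj0.csv traj1.csv traj2.csv --out-dir report/
```

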