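# osteocost

An incidence-based, bottom-up cost-of-illness model of osteoporotic
fractures, built as a reusable Python package.  It answers two questions
health economists and payers keep asking about osteoporosis: *what does a
person at risk cost over a lifetime once fractures start occurring*, and
*who carries that cost* — the hospital region, general practice, the
municipality, the patient, or the economy through lost productivity.

## The model

A deterministic Markov cohort model follows people aged 50–99 through ten
health states in one-year cycles:

```
well · wrist · post-wrist · vertebral · post-vertebral
first hip · post-first hip · second hip · post-second hip · death
```

Acute fracture states are one-cycle *tunnel* states carrying one-off event
costs (surgery, diagnostics, discharge services, sick days); the matching
post states carry the long-run elevated re-fracture and mortality risks and
continuing costs (pharmaceutical treatment, extra GP contact, personal care
after hip fracture).  A lifetime holds at most two hip fractures, enforced
structurally by the allowed-transition mask.  Transition probabilities are
built from epidemiological primitives with the standard transforms

- rate to one-cycle probability: `p = 1 − exp(−λ·t)`,
- relative risks applied on the hazard scale: `p' = 1 − (1 − p)^RR`,

and every future euro is discounted at 3 %/year
(`PV = c·(1 + r)^(−cycle)`).  Productivity losses use the human-capital
method: absence days (wrist 1 day, vertebral 4 days, hip 3 months) valued
at the gross daily wage by gender and age band, and for
fracture-attributable deaths before 65 the discounted remaining wage
stream to retirement.  Per-person discounted lifetime cost is decomposed
by health state and by payer (the two decompositions share one total by
construction), and scaled to a national annual burden with the at-risk
population by five-year age band.  A one-way sensitivity analysis
re-runs the pipeline at low/high bounds of any configuration scalar and
ranks parameters by outcome span (tornado ordering).

Because the registry microdata behind the original Danish analysis are not
distributable, a synthetic-data module generates inputs with the same
structure: log-linear incidence in age (hip steepest, female ≥ male for
wrist and hip), Gompertz–Makeham mortality, literature-scale relative
risks, and a demography whose at-risk counts calibrate exactly to the
published cohorts of 149,466 men and 388,474 women.

## Worked example

```sh
osteocost generate --out demo/inputs --seed 1
osteocost run --inputs demo/inputs --out demo/results
osteocost sa  --inputs demo/inputs --out demo/sa
```

The `run` step prints

```
male: lifetime cost EUR 2,106.21, most costly age 99
female: lifetime cost EUR 4,119.15, most costly age 99
```

and writes `lifetime_cost_by_state.csv`, `lifetime_cost_by_payer.csv`,
`national_burden_by_age_band.csv` and `summary.json`.  Under the default
synthetic inputs the per-person incremental lifetime cost is EUR 2,106
for men and EUR 4,119 for women, 92.0 % and 91.1 % of it accrued in the
four hip-related states, and the implied national annual burden is
EUR 186.2 million (36.1 M men, 150.1 M women).  Synthetic incidence
levels are deliberately structural rather than calibrated to any national
registry, so these magnitudes exercise the machinery; the *shapes* —
hip-state dominance, the municipality as the largest payer, women's total
burden exceeding men's under the female-skewed at-risk fraction — are the
properties the model is designed to reproduce.  The sensitivity step
ranks 29 scenarios and prints

```
baseline outcome EUR 4,119.15 over 29 scenarios
widest bar: pathways.personal_care_hours_per_week (span EUR 944.83)
```

— weekly personal-care hours (varied 3.4–6.55 h/week) dominate the
tornado, followed by the personal-care hourly price.

The same workflow is available as library calls
(`osteocost.run_analysis`, `osteocost.one_way_sa`) on in-memory objects.

## Layout

| module | contents |
| --- | --- |
| `osteocost.states` | the ten health states and the allowed-transition mask |
| `osteocost.markov` | transition tables, cohort stepping, discounting, microsimulation oracle |
| `osteocost.transitions` | rate/risk transforms and table assembly from epidemiology inputs |
| `osteocost.costs` | unit costs, care pathways, payer ledgers, productivity costing |
| `osteocost.pipeline` | lifetime cost decompositions and national aggregation |
| `osteocost.sensitivity` | one-way scenario analysis and tornado ranking |
| `osteocost.synthetic` | seeded generator for registry-like inputs |
| `osteocost.cli` | `osteocost generate / run / sa` |

See `docs/methods.md` for modelling assumptions, parameter provenance and
known limitations.
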