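# Methods

This note documents the model implemented in `osteocost`: its structure,
the provenance and meaning of its parameters, the numerical conventions,
the design choices made where the published description left the design
open, and what the synthetic inputs do and do not establish.

## State space and transition structure

The model is a deterministic Markov cohort model over ten health states —
well; acute and post states for wrist, vertebral and first/second hip
fracture; absorbing death — advanced in one-year cycles from age 50 to a
horizon of 99.  One model is run per gender; transition probabilities are
stored as tables indexed by gender and single year of age, since fracture
incidence and mortality change with both.

Acute fracture states are one-cycle tunnel states: absent a new fracture
or death, their entire occupancy moves to the matching post state after
one cycle.  This attaches one-off event costs and the fracture-year
mortality excess to the fracture year, and gives the post states the
long-run memory (elevated re-fracture and death risks) that a memoryless
chain would otherwise lose.

The allowed-transition mask is severity-ordered: from well and from the
wrist/vertebral track one may fracture a wrist, a vertebra or a (first)
hip; from the hip track the only onward fracture is the second hip, and
fracture events of lower severity than the current track are not
represented.  Two properties motivated this default over a fully
connected alternative: (i) the two-hip-fracture lifetime cap becomes a
*structural* guarantee of the graph — no path, deterministic or
simulated, can accrue a third hip event or a second hip before a first —
rather than a soft convention; and (ii) it matches the documented
behaviour of the original model, which favours hip fractures over wrist
and vertebral ones.  The cost of the simplification is that wrist and
vertebral events occurring after a hip fracture are not costed, a
conservative omission.  The mask is plain data (`states.default_mask`)
and can be replaced wholesale; the validator then enforces whatever mask
is supplied.

## From epidemiology to probabilities

Inputs are incidence rates per fracture type (events/person-year),
background all-cause mortality rates, and state-dependent relative risks
of re-fracture and death (constants, not age-interacting — they come
from literature as constants).  Rates convert to one-cycle
probabilities by `p = 1 − exp(−λ)`.  Relative risks act on the hazard
scale, `p′ = 1 − (1 − p)^RR`, which stays inside [0, 1) for any RR > 0;
a probability-scale option (`p·RR`, capped) is available for comparison
since the published description does not say which scale was used.
Acute states carry their post state's relative risks: the excess begins
in the fracture year.

Row assembly: death probability first, then the permitted fracture
destinations, then the residual to the self/post destination.  If death
plus fractures exceed 1 (possible at extreme ages under large RRs), the
fracture probabilities are scaled down proportionally with a warning;
death is never scaled.  Every built table must pass the validator
(entries in [0, 1], rows summing to 1 within 1e−9, death absorbing,
masked entries exactly zero).

## Costing

All prices are 2011 EUR.  Every cost component is tagged with exactly
one of five payers — regional, general practice, municipal, patient,
productivity — so the by-payer decomposition is exhaustive by
construction and must (and does, to 1e−6) reproduce the by-state total.

**Event costs** (on entry to an acute state):

- *Wrist*: 25 % operated (orthopaedic tariff), 75 % emergency-room care,
  one DXA scan — regional; 25 % referred to physiotherapy, priced at the
  municipal rehabilitation hourly rate (no separate tariff exists; the
  default is five one-hour sessions).
- *Vertebral*: 10 % treated in hospital (a configurable 50/50 mix of
  vertebroplasty and conservative medical treatment, plus DXA), 40 %
  managed by the GP (GP fee; pain-relief medication charged 100 % to the
  patient), 50 % undiagnosed and costless.  Pain relief has no published
  unit price; `pain_relief_annual` defaults to a synthetic EUR 40/year.
- *Hip* (first and second): surgical mix — 82.3 % (men) / 75.4 % (women)
  internal fixation, split 50/50 between the two fixation tariffs
  (the case mix between them is unpublished and configurable), remainder
  alloplastic — plus DXA, regional.  Municipal: standard rehabilitation
  (96.3 % of patients, 2 h/week for 13 weeks), respite care (5 % of
  patients, 26.8 days), the incremental nursing-home stay (5 % of
  patients, 2 years) net of the patient co-payment (midpoint 15 % of the
  published 10–20 % income-dependent band), food service (12 % of
  patients, daily deliveries), and 75 % of the assistive-device bundle
  (eight devices, default full uptake per hip fracture — a deliberately
  conservative-high choice since per-device uptake is unpublished); the
  remaining 25 % of devices is regional.  Patient: respite, nursing-home
  and food co-payments.  Social services and assistive devices attach
  only to hip states — wrist and vertebral fractures were judged not to
  increase those needs over the background population.
- The nursing-home stay is billed in full at the event cycle rather than
  spread over its two years; the discounting error this introduces is
  below 3 % of that component.

**Continuing costs** (per year of residence in a post state):
anti-osteoporotic pharmaceuticals (gender-specific annual price,
reimbursed 75 % by the region, 25 % patient), weighted by treatment
persistence — the published persistence schedule is not printed, so the
default is a geometric 0.7/year over five years, entering as its mean
(the model cannot condition on time-since-fracture within a post state,
so the schedule collapses to a scalar weight); incremental GP contact
(15.7 % of the annual fee); and, in post-hip states only, incremental
personal care (16.6 % of patients × 3.7 h/week × 52 × hourly rate).
The original results show small nonzero costs in the well state without
saying which components accrue there; the pharma/GP components can be
attached to well via `well_continuing`, off by default.

**Productivity** (human-capital method, zero at or beyond retirement age
65, weighted by a labour-force participation rate whose national value is
unpublished — synthetic default 0.75): fracture events cost absence days
(wrist 1, vertebral 4, hip 3 months ≡ 65 working days) at the gross
daily wage for the gender/age band; premature death costs the discounted
annual wage stream (daily wage × 220 working days/year) from the age at
death to 65.  Death-related loss is attributed at the fracture event as
the *excess* fracture-year death probability (mortality under the
state's RR minus background) times that stream — the incremental-cost
perspective requires counting only deaths attributable to the fracture.
Excess mortality in later post-fracture years is not separately
monetised; productivity cost is therefore conservative.

## Discounting and cycle accounting

Costs discount at 3 %/year, `(1 + r)^(−cycle)`, with cycle 0 the start
age.  There is no half-cycle correction by default (consistent with
conventional cohort-software accounting): continuing costs accrue on the
occupancy of each cycle, event costs at the cycle of entry, both
discounted by that cycle's index.  Setting `DiscountSpec(half_cycle=True)`
discounts continuing costs at `cycle + 0.5` (membership counted
mid-cycle) while event costs stay at the entry cycle.

## Aggregation

Per-person discounted lifetime cost comes from a unit cohort starting
well at 50.  National aggregation multiplies the at-risk population of
each five-year band (17.7 % of men and 40.8 % of women over 50) by the
modelled *annual* per-alive-person cost at the band's ages — the
interpretation consistent with reporting the burden per calendar year by
current age.  The printed per-person lifetime costs times the cohort
sizes do not reproduce the published national total, so the exact
published aggregation is ambiguous; a lifetime × cohort mode is provided
behind `mode="lifetime"` and labelled as the alternative interpretation.
Report rounding is EUR and percentage shares to 2 d.p., applied after
all summation checks.  The most-costly-age utility takes the argmax of
the annual cost series, ties to the younger age.

## Validation protocol

A per-individual microsimulation of the same transition tables serves as
an independent stochastic oracle (tests only).  At n = 50,000 over the
full 50-cycle horizon there are 500 (cycle, state) occupancy cells; the
binomial 3-standard-error band covers each with ≈99.7 % probability, so
a correct engine still leaves ~1–2 cells outside it in a typical run.
The agreement check therefore asserts the band at its nominal coverage —
at least 99 % of cells inside 3 SE — plus a family-wise 5-SE ceiling on
every cell, with a 10-count allowance absorbing discreteness in
near-empty states.  This formulation passes for any seed when the
engine is unbiased and fails under systematic error.  The same
simulation verifies the structural hip cap (no path exceeds two hip
events; no second hip before a first) and the tracker counts used to
compare modelled fracture numbers against input incidence.

## Synthetic inputs

The generator emulates the statistical structure of the registry inputs,
not their levels: log-linear incidence in age per fracture type with hip
the steepest (base rates at 50 of 1.0/0.8/0.4 per 1,000 person-years for
men and 3.0/1.2/0.6 for women for wrist/vertebral/hip; slopes
0.030/0.050/0.110 per year), Gompertz–Makeham mortality (male
0.001 + 0.004·e^{0.095·(a−50)}, female 0.0008 + 0.0025·e^{0.100·(a−50)}),
re-fracture RRs around 2 and post-hip mortality RRs of 2.5/3.0, a
population pyramid declining 4.5 %/year of age, and wage tables at the
published values.  A single integer seed drives the only randomness — a
mild lognormal jitter (sd 0.05) on each fracture type's base rate,
shared across genders so the female-at-or-above-male ordering and
within-curve monotonicity hold exactly.  At-risk counts calibrate to the
published cohorts by largest-remainder rounding, summing exactly to
149,466 men and 388,474 women.

Consequently, passing tests establish that the machinery is correct —
conservation, payer exhaustiveness, decomposition consistency, hip-state
dominance, tornado behaviour — not that the synthetic magnitudes match
Danish reality: per-person lifetime costs under the default synthetic
inputs (EUR ≈2,100 men / ≈4,100 women) sit well below the published
values because synthetic incidence is deliberately uncalibrated, and the
gender ordering reverses because the true male/female differences in
treatment cost and incidence shape are not reproduced.  The published
per-state and per-payer tables enter separately, as fixtures that the
reporting arithmetic must reproduce exactly.

## Known limitations

- Wrist/vertebral events after a hip fracture are neither simulated nor
  costed (severity-ordered mask).
- Persistence, participation, pain-relief price and device uptake are
  synthetic defaults where no value is published; all are configurable.
- No probabilistic (second-order) sensitivity analysis, no semi-Markov
  timing within a cycle, no informal-care or quality-of-life valuation,
  no currency or inflation indexing.
- The one-way sensitivity analysis perturbs one scalar at a time;
  correlated parameter movements are out of scope.

## Problem sizes

Default runs propagate 50 cycles × 10 states per gender and re-run the
full pipeline twice per sensitivity scenario; the shipped scenario set
(29 scenarios) completes in seconds, and the microsimulation oracle uses
50,000 individuals.
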