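# Methods

## The decision problem

Residents of residential aged care facilities (RACFs) are admitted to
hospital at high rates, and many of those admissions are avoidable if early
deterioration ("sub-acute" episodes such as urinary tract infections,
pneumonia or dehydration) is detected and managed within the facility.
`hospavoid` models the one-year cost-effectiveness of a nurse-led
hospital-avoidance program in a 96-bed facility, from the perspective of a
health system that funds both the aged-care per diem and hospital care.
Two strategies are compared:

* **usual care** — a deteriorating resident is transferred to hospital
  directly;
* **intervention** — trained nursing staff, supported by decision tools and
  diagnostic equipment, manage sub-acute episodes within the facility,
  admitting only those that cannot be resolved on site.

## Markov cohort model

A discrete-time Markov cohort model with **daily cycles** follows the
expected state occupancy of a closed cohort of 96 residents over 365 days.
Four states: `STABLE` (in the facility), `SUBACUTE` (a one-day episode of
managed deterioration; intervention arm only), `HOSPITAL`, and absorbing
`DEAD`.

Each cycle, death competes first: every alive resident dies with daily
probability `p_death` regardless of state, and the care transitions apply
to survivors, so e.g. the usual-care stable-to-hospital entry is
`(1 − p_death)·p_admit_direct` and every row sums to one without
renormalisation.  Under the intervention, a stable resident enters
`SUBACUTE` with probability `p_subacute_onset`; the episode lasts exactly
one cycle and resolves back to `STABLE` unless it is not managed in the
facility (probability `1 − p_treat_in_facility`) *and* leads to an
admission (probability `p_admit_from_subacute`), giving a per-episode
admission probability of `(1 − 0.670)·0.722 = 0.238` at base case.
Hospital stays end in discharge with a daily probability, so sojourns are
geometric.

Tallies per cycle: admissions (flow into `HOSPITAL`), hospital bed days
(`HOSPITAL` occupancy summed over cycles), sub-acute episodes (flow into
`SUBACUTE`).  Costs: the RACF per diem accrues for **all alive residents
including days in hospital** (the facility bed is retained); the hospital
per diem per bed day; an ambulance transfer per admission; and, in the
intervention arm only, the annualised diagnostic-equipment cost
($1714 + $351 + $277 = $2342/year, capital purchases spread straight-line
over a 7-year useful life) added once regardless of utilisation.  QALYs
weight facility/sub-acute person-days by utility 0.514 and hospital
person-days by 0.44, with 365 days = 1 year.  No half-cycle correction
(negligible at daily resolution) and no discounting (12-month horizon).

The incremental comparison reports Δcost, ΔQALYs, a cost-effectiveness
plane classification ("dominant" requires strictly more QALYs at strictly
lower cost), and Net Monetary Benefit `NMB = λ·ΔQALY − ΔCost` at
willingness to pay λ ($28,000/QALY by default, $0 as a sensitivity),
expressed per resident by dividing by the cohort size.

### Key modelling choices (and why)

* **Closed cohort, deaths not replaced.**  With a daily death probability
  of 0.0011 about a third of the cohort dies within the year; survival
  weighting is what brings total QALYs to ≈ 40 rather than the 49.3 of an
  immortal cohort.  A consequence is that expected event counts carry the
  same ≈ 18 % attrition factor, so modelled admissions (≈ 21 intervention /
  29 usual care at base case) sit below the no-attrition products
  96·365·rate (≈ 25 / 35).
* **One-day sub-acute state.**  The alternative — letting untreated
  episodes persist and retry admission daily — would push the per-episode
  admission probability towards `p_admit_from_subacute` itself (0.722) and
  roughly triple intervention admissions, which is inconsistent with the
  other inputs; the one-day reading keeps episode counts and admissions
  mutually coherent.
* **Shared death probability across states and arms** (a single tabled
  value applies to all residents), which makes alive person-days identical
  across arms and cancels the RACF per diem out of the incremental cost.
* **Discharge probabilities are taken as given** (0.283 / 0.151 daily).
  Their geometric means (3.5 / 6.6 days) do not equal the observed mean
  stays (4.8 / 7.7 days); no attempt is made to re-derive one from the
  other, and bed-day outputs inherit this tension.

## Parameter estimation

Daily transition probabilities are estimated as **events per person-day**
with the facility's average occupancy as denominator: 112 sub-acute
episodes / (94·365) → 0.003; 45 admissions / (94·365) → 0.001; the treated
fraction 75/112 → 0.670 (all rounded half-up to 3 decimals when the table
is reproduced; full precision kept internally).  Uncertainty distributions
are moment-matched: a normal for annual admission counts, a gamma for
length of stay (`shape = mean²/var`, `scale = var/mean`), and a beta for
probabilities and utilities (`α = m·ν`, `β = (1−m)·ν`,
`ν = m(1−m)/sd² − 1`), each reproducing its input moments exactly.  An SD
infeasible for a beta (sd² ≥ m(1−m)) raises an error stating the bound; an
opt-in variance cap at 0.95·m(1−m) logs a warning instead.

## Probabilistic sensitivity analysis

1000 Monte Carlo draws; per draw, every parameter is sampled once, both
arms are evaluated through the cohort engine, and NMB is recorded at each
willingness-to-pay value.  Assignments: beta for probabilities and
utilities (moment-matched on the tabled mean/SD); normal for unit costs
with the 95 % CI spanning ±20 % of the base case (sd = 0.20·mean/1.96),
truncated at zero by resampling; gamma (mean 1807, SD 1028) for the
hospital bed-day cost.  Parameters shared between arms (death probability,
unit costs, utilities) reuse the same draw in both arms within a
realisation, so no spurious incremental noise is injected;
`shared_arm_draws=False` (CLI `--independent-arms`) disables this.  A
tabled SD of exactly zero makes a parameter degenerate, and an
all-SDs-zero analysis reproduces the deterministic base case exactly.

### A caution on the shipped rate SDs

Several tabled rate SDs are much larger than their means (0.004 on 0.001;
0.007 on 0.003; 0.388 on 0.670).  The moment-matched betas then have
α ≪ 1: most draws are essentially zero and a long upper tail carries the
mean.  The resulting NMB distribution is extremely heavy-tailed — its
median is slightly negative (in most draws neither arm generates
admissions and the intervention pays the equipment cost for nothing),
only ~25–30 % of draws are positive, the per-draw SD is of order
$20,000/resident, and the 1000-draw mean has a Monte Carlo standard error
near $700/resident, so headline PSA numbers move materially between
seeds.  These SDs appear to describe day-to-day count variability rather
than sampling uncertainty of the annual rates; users with access to raw
event data should prefer SDs on the scale of the estimator's standard
error (for a daily rate estimated from person-days `N`, `√(p(1−p)/N)`),
under which the NMB distribution concentrates near the base case.  The
package deliberately samples exactly what the table specifies and leaves
the choice of SDs to the input table.

## Synthetic event logs

The generator is a per-resident Bernoulli microsimulation of the same
transition structure (not cohort expectations), so the estimation layer
gets realistic integer counts: 96 beds, two 365-day periods (one per arm),
daily sub-acute onsets / direct admissions at the base-case rates,
geometric hospital sojourns, daily mortality with no replacement of the
dead.  Day 0 is the initial all-stable day; each later day is evaluated
death-first so nobody dies and transfers on the same day.  All draws come
from one seeded `numpy` Generator in a fixed per-day order (death uniforms
for residents in id order, then primary care-transition uniforms, then
secondary uniforms for admission from an untreated episode), making logs
bit-reproducible.  Logs serialise as tidy CSV
(`resident_id, day, state, event, episode_id`); an episode's onset and any
resulting admission share an `episode_id`.

What the generator does *not* emulate: resident covariates (age, sex,
dementia status), seasonal or weekday patterns, bed refills after death,
multi-day sub-acute episodes, or facility-level overdispersion.  Tests
passing on synthetic logs therefore demonstrate internal consistency of
estimation and simulation, not fidelity to any real facility.

One identifiability note: a log records whether an episode *ended* in
admission, not the latent treated-in-facility decision, so
`n_treated_in_facility` counts episodes without a subsequent admission and
only the compound per-episode admission probability
`(1 − p_treat)·p_admit` is recoverable from data; the two factors are
separately meaningful only as inputs.

## Numerical notes

* Transition rows are validated to sum to 1 within 1e−12; cohort occupancy
  is conserved to better than 1e−9 per cycle and matches an independent
  matrix-power/fundamental-matrix oracle to 1e−9.
* Rounding for table reproduction is decimal half-up, not banker's.
* Monte Carlo sizes in the test suite (200-seed simulation means, 10-year
  recovery runs, 1e5-draw moment checks, a 5000-draw convergence run) were
  chosen to keep each check's sampling error an order of magnitude below
  its tolerance while the full suite stays inexpensive.
* Degenerate inputs: zero-variance gamma fits are rejected (a gamma cannot
  be a point mass); probabilities of 0 or 1 are legal everywhere; an
  all-zero scenario yields an event-free log and an identity cohort.

## Known limitations

* The bed-day and admission outputs embed the discharge-probability /
  mean-stay tension noted above; both cannot match observation at once.
* Single facility-wide parameters: no resident heterogeneity, no
  correlation structure between parameters in the PSA.
* One-year horizon only; equipment annualisation is the only multi-year
  element.
* The heavy-tailed PSA under the shipped SDs (see the caution above) makes
  1000-draw summaries seed-sensitive; report seeds alongside results.
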