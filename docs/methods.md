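# Methods

## Model structure

A discrete-time Markov cohort model with monthly cycles and three
mutually exclusive states — stable disease, disease event, death. All
patients enter in stable disease on first-line treatment. Each cycle a
stable patient may have a disease event (probability *p*<sub>SE</sub>) or
die (*p*<sub>SD</sub>); a patient in the event state may die
(*p*<sub>ED</sub>). Events are absorbing short of death: after an event
the patient discontinues first-line therapy, switches to the opposite
regimen as second line, and remains in the event state, with mortality
governed by *p*<sub>ED</sub> of the first-line regimen's calibration
regardless of the second-line drug. Third-line/salvage therapy, background
(other-cause) mortality, age structure and quality-of-life outcomes are
not modelled. Transition probabilities are constant over time and
treatment phase.

Fractional patients are carried everywhere; integer headcounts and
€100-rounded euro amounts exist only in display output. Cohort mass is
conserved to 1e-9 at every cycle (asserted at run time).

### Horizon, cohorts, mid-year entry

The horizon is 36 months (three budget years). One cohort of newly
eligible patients enters per year. To approximate uniform accrual through
the year, each cohort enters at its year's midpoint (calendar months 7,
19, 31) — the "everyone starts July 1" convention — rather than a
trapezoidal half-cycle correction. A cohort therefore contributes 6, 18
and 30 cycles to the horizon depending on its entry year. Costs are
attributed to the calendar year in which they accrue and are not
discounted, consistent with short-horizon budget-impact practice.

### Treatment phases

ATO+ATRA: 1 induction + 7 consolidation months (8-month course), no
maintenance. ATRA+chemotherapy: 1 induction + 3 consolidation + 24
maintenance months (28-month course). After the course, stable patients
move to a post-treatment monitoring phase (per-cycle medical cost) through
the horizon. Durations are config-overridable.

## Calibration

Monthly EFS/OS series are placed on an integer month grid by
last-observation-carried-forward evaluation (Kaplan-Meier estimates are
step functions; non-monotone raw input is rejected, not repaired). The
objective is the summed percent absolute deviation of the model-implied
EFS and OS from the observed series over months ≥ 1, equal weight on both
curves over the full series; months with observed survival 0 are excluded
(denominator guard). Optimisation is Nelder–Mead with proposals clipped
into [0,1] (and the stable-exit probability into ≤ 1) plus a penalty
proportional to the violation, run from a moment-based deterministic
start plus a configurable number of seeded random interior starts
(default 10); objective tolerance 1e-14, coordinate tolerance 1e-12.

Because EFS and OS alone identify *p*<sub>SD</sub> and *p*<sub>ED</sub>
only weakly (the event-state occupancy that separates them stays small),
the default fit ties *p*<sub>SD</sub> = *p*<sub>ED</sub> — the published
per-regimen estimates are equal, consistent with that form. The untied
3-parameter fit is available (`tie_death_probs=False`). On noiseless
54-month curves the tied fit recovers generating probabilities to
≈1e-8; the acceptance suite requires 1e-4.

## Synthetic survival data

`deterministic_curves` evaluates the cohort recursion exactly.
`sampled_curves` simulates patient-level histories: time-to-leaving-stable
is geometric with parameter *p*<sub>SE</sub>+*p*<sub>SD</sub>, the exit is
fatal with conditional probability *p*<sub>SD</sub>/(*p*<sub>SE</sub>+*p*<sub>SD</sub>),
and a non-fatal event is followed by a geometric time to death with
parameter *p*<sub>ED</sub>. No censoring is simulated (the curves serve
only as calibration targets), so the empirical survival proportions equal
the Kaplan-Meier steps. What the generator does **not** emulate:
digitisation error of reading curves off a published figure, staircase
coarsening from small trial risk sets, censoring before the analysis
cut-off, and any non-geometric (time-varying) hazard. Passing the sampled
recovery test therefore shows robustness to sampling noise at trial scale
(n = 500 is realistic for a two-arm phase 3 APL trial read monthly), not
to digitisation artefacts.

## Cost accounting

Five components per cohort and calendar month, each weighted by the
stable-state occupancy at the *start* of the cycle (the entering cohort
pays induction in full):

- **pharmacy** — phase totals spread uniformly over the cycles of the
  phase (maintenance is a direct monthly amount);
- **medical** — per-cycle amounts by phase, including post-treatment
  monitoring (€94/cycle) through month 36;
- **adverse events** — expected cost (probability × unit cost summed over
  neutropenia, thrombocytopenia, hepatic toxicity, fever of unknown
  origin) in the induction month and the first three consolidation
  cycles, the phases for which trial AE rates exist; later consolidation
  months carry no AE cost;
- **disease event** — €430 once per incident event, in the event month;
- **second line** — the opposite regimen's full course cost, spread
  uniformly over that regimen's treatment duration, starting the month
  *after* the incident event, truncated at month 36, and not reduced for
  deaths during second line.

### Pharmacy phase allocation (reconstructed)

The published inputs give only course-level pharmacy totals (€46,814
ATO+ATRA; €6,832 ATRA+chemotherapy). The phase split matters for the
yearly attribution and for the sensitivity analysis, so the base
configuration stores an explicit allocation:

- **ATO+ATRA**: consolidation €34,816 (the sensitivity-analysis base
  value implied by its printed ±25 % bounds €26,112/€43,520), remainder
  €11,998 to induction. This reproduces the published per-patient yearly
  pharmacy split (€36,800 / €9,900 / €0) exactly at display rounding.
- **ATRA+chemotherapy**: maintenance ≈€140/month, reconstructed from the
  published yearly pharmacy rows (≈€1,600 in year 2 ≈ 12 maintenance
  months; ≈€1,200 in year 3 ≈ 10 months), remainder €3,472 spread
  uniformly over induction + consolidation (months 1–4). A uniform
  €6,832/28 per-month spread was considered and rejected: it puts only
  ≈€1,400 in year 1 against the published €3,700 and loses ≈€200 of the
  cumulative to attrition-weighting. Maintenance drug cost of ≈€140/month
  is also pharmacologically plausible for low-dose 6-mercaptopurine +
  methotrexate + intermittent ATRA at Italian reimbursement prices.

Both splits are ordinary config fields and can be overridden. By
construction a patient completing the course inside the horizon accrues
exactly the course total, independent of the split.

### Second-line course cost

The second-line totals are derived compositionally as the opposite
regimen's first-line pharmacy total plus its on-treatment medical costs:
€57,185 for an ATO+ATRA course (matching the published second-line figure
exactly) and €37,466 for an ATRA+chemotherapy course (published €37,472;
the €6 difference is below display rounding). Deriving rather than
storing the totals makes the sensitivity analysis propagate a
consolidation-cost perturbation into second-line spending, which the
published sensitivity range requires. An explicit `second_line_total`
override is available per regimen.

The one-month lag between an event and the first second-line cycle is the
natural Markov accounting (a patient transitioning during month *m* is in
the event state from month *m*+1) and is what the published year-1
figures support; with a same-month start the reference-scenario year-1
total overshoots by ≈0.3 %.

## Scenarios and budget impact

Reference scenario: ATRA+chemotherapy holds 100 % of the market in all
three entry years. New scenario: 10/20/30 % of each year's entering
cohort starts ATO+ATRA. Shares apply to newly entering cohorts only;
nobody switches first-line regimen mid-course. The eligible cohort
(≈81.82/year) is held constant across entry years. Net impact is
post-minus-pre per calendar year, exact to the cent before display
rounding; the percent increase divides by the same-year reference total.
Scenario costs are linear in cohort sizes and uptake shares (property-
tested), so per-patient differences scale directly to the population.

## One-way sensitivity analysis

Seventy registered scalars (funnel, uptake shares, transition
probabilities, phase-level pharmacy and medical costs, disease-event
cost, all AE probabilities and unit costs) are varied one at a time to
×0.75 and ×1.25 of base, the paired scenario comparison is rerun, and
parameters are ranked by the spread of the third-year net impact.
Probabilities perturbed outside [0,1] are clamped with a logged warning.
Phase-level costs perturb as one unit (grouped tariff lines). The top of
the tornado is the ATO+ATRA consolidation-phase cost
(≈€285,800–€659,300 across its ±25 % range, against a published
€290,100–€665,600), followed by the four funnel parameters that scale
the eligible population.

## Numerical conventions

- Display rounding: nearest €100 (euro tables), nearest integer
  (headcounts); applied at report time only.
- Year boundaries: calendar months 1–12, 13–24, 25–36.
- Degenerate inputs: zero-cost and zero-probability configurations are
  valid; an empty cohort yields an all-zero trace; a zero-month
  second-line duration contributes nothing.
- Tie-break in the tornado ranking: alphabetical by parameter name.

## Known limitations

- The published year-3 headcount table (207 stable / 11 events / 27 dead
  in the reference scenario; 22 dead in the new scenario) is not
  reproducible from the published monthly transition probabilities under
  the mid-year entry convention, although the year-1 and year-2 rows are
  (79/1/2 at cohort month 6; 152/4/8 at months 18/6), and the cost tables
  — which depend on the same occupancies — are reproduced to ≲1 %.
  The implied year-3 exposure (≈39/27/15 cohort-months) matches neither
  mid-year (30/18/6) nor full-year (36/24/12) accounting. This package
  reports the internally consistent values (19 dead pre, 16 post at
  month 36) and flags the published row as irreproducible rather than
  special-casing it.
- Annual (as opposed to cumulative) cost splits depend on the
  reconstructed pharmacy allocation and are approximate at the €100
  level.
- Supportive-care complication costs, high-risk APL patients,
  cost-effectiveness/QALY outcomes and probabilistic sensitivity
  analysis are out of scope.
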