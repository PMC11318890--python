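# Methods

## Model overview

`perinatal-roi` is a deterministic, annual-interval cost-benefit calculator
for scaling a two-stage screening programme plus psychosocial interventions
(PSIs) for common perinatal mental health problems (depression, anxiety) in
Malawi over 2022–2026. It takes a societal perspective: government costs
(staff, training, supervision, travel reimbursement) and costs borne by
women (out-of-pocket travel) are both counted, as are productivity gains.
There is no randomness anywhere in the model; identical inputs yield
bit-identical outputs.

The pipeline per calendar year is:

1. **Cascade** — population → live births → antenatal/postnatal women →
   first-stage screenings → second-stage screenings → women treated.
2. **Workforce** — screening/treatment minutes → workdays → whole FTEs →
   staff cost.
3. **Training & supervision** — train-the-trainer cascade costs for new
   staff, refresher courses, and ongoing supervision.
4. **Travel** — journeys by women (clinic delivery) or providers
   (community delivery).
5. **Benefits** — depression and diarrhoea episodes averted, DALYs,
   healthcare savings, productivity gains, stunting cases averted.
6. **Economics** — MWK→USD conversion, totals, net benefit, NPV, ROI.

## Key assumptions and formulas

**Demography.** Live births = population/1,000 × crude birth rate. The
2020–2025 rate (35.5) applies through 2025 and the 2025–2030 rate (36.0)
from 2026; this regime split reproduces the published live-birth series at
both ends (718,023 in 2022; 816,444 in 2026). Antenatal women are all
pregnancies — live births inflated by 1/(1 − stillbirth probability,
2.4%); postnatal women are mothers of live births surviving the perinatal
period — deflated by (1 − maternal mortality, 0.3%).

**Screening cascade.** Every clinic visit (4 antenatal at 90% access,
1.2 postnatal at 72% access) carries one 2-minute first-stage screen,
scaled by a coverage that rises linearly 80%→100% over the five years
(a learning effect). 24% of first-stage screens are positive and receive
the 10-minute second-stage screen; the second-stage positivity rises from
12% to 22% (improving identification); 95% of positives accept treatment.
A PSI course is five sessions, 37.5 min individual or 75 min for a group
of six.

**Workforce.** Demanded minutes are converted to workdays at the cadre's
scheduled day (8 h professionals, 6 h counsellors/volunteers) *without*
the direct-time ratio; the 80% direct-time ratio enters only when
converting workdays to FTEs over 220 working days/year. This split is the
only one that reproduces both published 2022 values (9,295 first-stage
days and 53 professional FTEs) from 2,230,858 screenings. FTEs are rounded
up — staffing must cover demand — and cost salary × 12 × 1.15 overhead,
converted at the model exchange rate. Second-stage screening and treatment
minutes are pooled into one volunteer workload, matching how the cadre is
reported.

**Training.** One master trainer (clinical psychologist, MWK 2,273/h =
400,000/month ÷ 22 days ÷ 8 h) trains trainers (assistant counsellors,
MWK 1,364/h) in classes of 12.5 over 76 h; trainers train front-line
deliverers in classes of 5 over 105.5 h and supervise them 44 h/year.
Trainee attendance time is costed at the trainee's own hourly wage derived
from their scenario salary by the same 22 × 8 convention (a volunteer at
US$40/month is MWK 129/h at the 568 MWK/USD rate). Year one trains the
whole initial workforce; later years only the increment. Refresher courses
(16 h) run 2023–2025 for the existing workforce, in trainer-course-sized
classes with one trainer fee per class — the class size for refreshers is
not independently documented, so the regular course size is reused.

**Travel.** A "journey" is one single trip, priced at MWK 300. Clinic
delivery: the woman travels once per session (group members each attend in
person). Community delivery: the provider travels once per woman-session
(individual) or once per group session, i.e. 1/6 journey per woman-session
(group). Group sessions at clinics need no provider journey (the provider
is on-site). Screening visits generate no travel cost — they occur at
visits women make anyway.

**Benefits** (one-year horizon only; consequences accrue in the delivery
year). Depression episodes averted = treated × 6% (the remission
difference, 50% vs 44%); mother DALYs = episodes × disability weight 0.40
× 0.5 years. Diarrhoea episodes averted = treated × 11%; child DALYs use
weight 0.19 × 1.44/365 years (a 365-day year; 365.25 would change the
result by <0.1%). Healthcare savings price averted diarrhoea episodes at
MWK 32,359. Productivity: 0.765 + 1.02 extra workdays per treated woman at
MWK 455/day. Stunting cases averted (treated × 5%) are reported but never
monetized — there is no defensible same-year price for them. Reductions in
excess maternal mortality are not modelled.

**Economics.** All four cost categories sum in MWK and convert to USD.
Net benefit = (DALY value + healthcare savings + productivity) − total
costs, undiscounted. NPV deflates the net benefit by the cumulative CPI
factor (inflation of the years *after* the base year, 2022) and then
discounts at 3%. ROI = benefits ÷ costs, so ROI ≥ 1 exactly when net
benefit ≥ 0. USD figures are reported in whole dollars, ratios to two
decimals; all counts round half away from zero at each reported quantity,
with full precision kept in between.

## Calibrated constants

The source analysis reports both MWK and USD totals but never an exchange
rate, and values DALYs in USD without stating the price. Both constants
are therefore calibrated once from the published 2022 column and fixed as
defaults:

- `mwk_per_usd = 568.0` — ratio of the published 2022 total costs,
  372,763,394 MWK / 656,274 USD = 568.00.
- `usd_per_daly = 321.5` — published 2022 health benefit over DALYs,
  362,002 / 1,126 = 321.49. (The listed GDP per capita, US$544 in 2022,
  does not reproduce the published health-benefit row, so the monetization
  rule is not GDP-based.)

Both are ordinary parameters and can be overridden in the parameter file.

## Known discrepancies with the published results table

Several published rows cannot be reproduced from the publication's own
stated formulas; the calculator implements the documented formulas and
surfaces the gaps as deterministic report warnings rather than imitating
undisclosed adjustments:

- **First-stage screenings**: the documented visit arithmetic gives
  2,613,564 for 2022; the published table prints 2,230,858 (~15% lower).
  The extra factor is not disclosed. A `calibration_factor` hook on the
  cascade (default 1.0, never applied silently) lets users rescale
  volumes to match the published series.
- **Women treated**: published 92,219 for 2022 is inconsistent with
  535,406 × 12% × 95% ≈ 61,036; the published downstream benefit rows are
  consistent with the larger figure, the upstream rows with the smaller.
- **Staff cost**: published 2022 staff cost (260.4M MWK) is roughly twice
  FTE × scenario salaries; the salary assumptions behind the row are
  unrecoverable.
- **Training cost**: the published 32.95M → 0.87M pattern implies course
  accounting beyond the documented per-course fees; the shape (large year
  one, small later years) is reproduced, the level is not.
- **NPV and ROI rows**: no disclosed transformation maps the published
  undiscounted net benefit (93,336 in 2022) to the published NPV (34,272)
  or the published ROI (1.05); both rows are treated as workbook-internal.
- The published 2024 aggregated MWK total is 1 MWK below the sum of its
  own printed components (rounding in the source workbook).
- Two structural near-matches confirm the cost formulas: supervision for
  121 volunteers (7,948,732 MWK, within 1.2% of the published 7,857,780)
  and travel for 61,036 treated women (72,480,250 MWK, within 1.3% of the
  published 71,597,676).

## Scenario levers and sensitivity analysis

Four levers mirror the decision-maker options: monthly salaries of the
first-stage screeners (default US$235) and of the PSI deliverers (default
US$40), and the group/individual and clinic/community delivery mixes
(each restricted to 0/25/50/75/100%). `one_way_sensitivity` re-runs the
projection along a value grid for one lever — an option name or a dotted
parameter path such as `econ.discount_rate` — holding everything else
fixed, and reports per-year net benefit, ROI and a negativity flag.
Benefits depend only on women treated, so salary and setting levers move
costs alone; the group/individual mix also moves volunteer workload and
hence training and supervision costs.

## Numerical conventions and degenerate inputs

- Rounding: half away from zero (`decimal`-based), applied to each
  reported count/amount; FTEs round up.
- Zero coverage yields a valid all-zero cascade; ROI is reported as
  absent (`None`) when costs are zero and 0.0 when only benefits are zero.
- Per-year series must cover exactly the modelled years; a partial series
  in an override file merges year-by-year into the defaults.
- Proportion levers off the five-level grid, unknown parameter keys, and
  bound violations all fail validation loudly; nothing is silently
  coerced.

## Limitations

- No workforce-capacity constraint on coverage (screening demand is
  assumed staffable), no rostering or attrition.
- No long-term (>1 year) consequences: stunting-related earnings losses,
  mortality reduction and multi-year remission are all out of scope.
- Single currency pair (MWK/USD); no venue, materials or per-diem costs
  in training.
- The model reproduces the published worked example only where that table
  follows its own documented formulas (see discrepancies above); users
  comparing against the published table should expect the warned rows to
  differ.
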