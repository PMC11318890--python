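# perinatal-roi

A deterministic cost-benefit calculator for scaling **two-stage screening
and psychosocial interventions (PSIs) for common perinatal mental health
problems in Malawi, 2022–2026**.

In Malawi roughly 30% of women experience depression or anxiety during
pregnancy or the first year after birth. A feasible response is
task-sharing: maternity staff give every clinic attendee a 2-minute
first-stage screen; trained, supervised volunteers give positives a
10-minute confirmatory screen and deliver a five-session psychosocial
intervention (e.g. the Thinking Healthy Programme), individually or in
groups, at the clinic or in the community. This package projects, year by
year, what scaling that programme nationally would require and return:
screening and treatment volumes, workforce (in whole FTEs), costs by
category in Malawi Kwacha (MWK), health benefits in DALYs averted and
USD, healthcare savings, productivity gains, and the headline **net
benefit** and **return-on-investment ratio**. It is intended for health
planners and health economists exploring scale-up scenarios.

## Model core

For year *t*, with `W(t)` women treated:

- cascade: `screenings₁(t) = visits(t) · coverage(t)`,
  `screenings₂(t) = 0.24 · screenings₁(t)`,
  `W(t) = screenings₂(t) · p₂(t) · 0.95`, with coverage rising 80→100%
  and second-stage positivity p₂ rising 12→22% over the five years;
- workforce: FTE = ⌈workdays / (220 · 0.8)⌉ per cadre; staff cost =
  FTE · salary · 12 · 1.15;
- benefits: ΔDALY(t) = `W(t)`·6%·0.40·0.5 (mothers) +
  `W(t)`·11%·0.19·(1.44/365) (infants); plus healthcare savings
  (MWK 32,359 per averted diarrhoea episode) and productivity
  (1.785 extra workdays per treated woman at MWK 455/day);
- economics: `NB(t) = B(t) − C(t)` (USD, undiscounted),
  `NPV(t) = NB(t) / Π(1+πₛ) / (1.03)^(t−2022)`, `ROI(t) = B(t)/C(t)`.

All inputs live in one validated YAML parameter book (shipped defaults =
the published national analysis); four scenario levers mirror the
decision-maker options: the two cadres' monthly salaries and the
group/individual and clinic/community delivery mixes (0/25/50/75/100%).
See `docs/methods.md` for assumptions, calibrated constants and known
discrepancies with the published worked example.

## Worked example

Default scenario — first-stage screeners at US$235/month, volunteer PSI
deliverers at US$40/month, 50/50 group/individual and clinic/community:

```sh
perinatal-roi --salary-psi 40 --prop-group 50 --prop-clinic 50 --out results.csv
```

The CSV has one row per quantity, one column per year. Headline rows:

| year | total costs (USD) | total benefits (USD) | net benefit (USD) | ROI |
|------|------------------:|---------------------:|------------------:|----:|
| 2022 | 539,816 | 828,149 | 288,333 | 1.53 |
| 2023 | 613,042 | 1,056,157 | 443,115 | 1.72 |
| 2024 | 742,288 | 1,397,374 | 655,086 | 1.88 |
| 2025 | 860,024 | 1,696,464 | 836,440 | 1.97 |
| 2026 | 1,025,666 | 2,157,846 | 1,132,180 | 2.10 |

Read: in 2022 the programme costs US$0.54M, returns US$0.83M in monetized
health and economic benefits (864 DALYs averted, mostly maternal
depression), for a net benefit of US$0.29M and US$1.53 returned per
dollar invested; by 2026 rising coverage and identification push the net
benefit to US$1.13M. The run also prints deterministic warnings naming
the rows where the published workbook used undisclosed internal
adjustments and this calculator's documented-formula results differ
(see `docs/methods.md`).

One-way sensitivity over the volunteer salary, and a chart:

```sh
perinatal-roi --sensitivity salary_psi_usd_month=40,50,200 \
              --out results.csv --plot summary.png
```

Net benefit falls strictly as the PSI salary rises; at US$200/month it is
lower than at US$40/month in every year. The same engine is available as
a library:

```python
from perinatal_roi import load_parameters, run_projection, ScenarioOptions

result = run_projection(load_parameters(), ScenarioOptions(prop_group=0.75))
print(result.economics[-1].net_benefit_usd)
```

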