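# cannrisk

First-tier toxicological risk assessment for additives in vaporized cannabis
concentrates — a library and CLI for regulators and manufacturers who need to
prioritize terpenes, flavors and other intentionally added ingredients for
acceptance, elimination, or higher-tier evaluation, without deep toxicological
expertise on staff.

## What it computes

The assessment follows the classical four-step template, specialized to
inhaled concentrate additives:

1. **Hazard screening.** Categorical exclusions applied before any
   arithmetic: respiratory sensitizers not native to the cannabis plant,
   Big-8 food-allergen sources, phenolic acetates (the vitamin E acetate /
   EVALI lesson), and supplements/vitamins/HPHCs are screened out.
   Cannabis-native sensitizers are instead capped at the plant-relative
   concentration `plant_ratio_to_THC × product THC (mg/g)`. Genotoxicity
   routes to the genotoxic TTC tier rather than excluding (a strict mode
   makes it an exclusion).

2. **Safety limit from a point of departure (POD).** For each usable
   NOAEL/NOAEC/LOAEL/LOAEC or regulatory limit:

   ```
   safety limit = POD_adj / (UF1 · UF2 · UF3 · UF4 · UF5 · UF6)
   ```

   where `POD_adj` adjusts for intermittent study schedules (× h/24 for
   inhalation, × d/7) and test-article purity, and the UFs are the standard
   defaults: interspecies 10, intraspecies 10 (3/1 for sensitive
   subpopulations), oral→inhalation 6 = 2 (kinetics) × 3 (dynamics),
   LOAEL→NOAEL 10, subacute→chronic 10 / subchronic→chronic 3, database
   completeness 1/3/10. A total UF above 10,000 refuses a numeric limit.
   Limits normalize to mg/day (× 60 kg body weight, or × 0.3 / 6.7 / 20 m³
   inhaled volume for 15-min / workday / 24-h windows); local-respiratory
   and systemic endpoints are governed separately and the lower limit wins.

3. **TTC routing** for data-poor substances: a five-question decision tree
   assigning 18 µg/day (organophosphates/carbamates), 1.5–120 µg/day
   (genotoxic, tiered by intended exposure duration), 865/145 µg/day
   (cannabis-native or GRAS substances by Cramer class), or 22.39/4.286
   µg/day (everything else, by OASIS mode of action).

4. **Exposure and risk characterization.**

   ```
   exposure (mg/day) = concentration (mg/g) × consumption (mg/day) / 1000
   max allowable concentration (% w/w) = limit (mg/day) / consumption (mg/day) × 100
   ```

   with a default consumption of **100 mg concentrate/day** — the mean of
   the 95th-percentile weekly (140 mg/day) and monthly (57 mg/day) daily
   averages observed in smart-vaporizer telemetry. Exposure at or below the
   governing limit is low risk; otherwise the report lists the three
   options: reduce/remove, refine the assessment, or generate data.

A synthetic telemetry simulator (`cannrisk.usage_sim`) generates device
usage logs with the observed structure — intermittent use (geometric
monthly use-day counts, mean 7.8, median 5, p95 24) and heavy-tailed
log-normal per-use-day consumption (median 44 mg, mean 151 mg) — so the
whole exposure pipeline is testable without any proprietary dataset.

## Worked example

`examples/linalool_like_terpene.json` describes a GRAS, cannabis-native
terpene with a rat subchronic oral NOAEL of 250 mg/kg-bw/day and
developmental data, proposed at 10 mg/g (1% w/w) in an age-gated 850 mg/g
THC concentrate:

```
$ cannrisk assess --dossier examples/linalool_like_terpene.json \
                  --context examples/product_context.yaml --concentration 10
First-tier additive risk assessment — linalool-like-terpene
  screening verdict: pass
  additive concentration: 10 mg/g (1% w/w)
  daily exposure: 1 mg/day
  governing limit: 8.33 mg/day (pod_derived)
  margin (limit/exposure): 8.33
  max allowable concentration: 8.33% w/w
  verdict: low_risk
```

Reading the numbers: the NOAEL divided by the UF product 1800
(10 interspecies × 10 intraspecies × 6 route × 3 duration) gives
0.139 mg/kg-bw/day, i.e. 8.33 mg/day at 60 kg. A 95th-percentile consumer
of 100 mg concentrate/day at 10 mg/g additive inhales 1 mg/day — an
8.3-fold margin below the limit — and the formulation could go as high as
8.33% w/w before reaching it. Exit codes (0 low risk, 2 exceeds, 3
excluded, 4 insufficient data) support batch screening; `--out` writes the
full audit-trailed JSON report.

Simulate and summarize telemetry:

```
$ cannrisk simulate --devices 200 --seed 7 --out log.csv
$ cannrisk summarize-usage --log log.csv
                                  mean     p50      p90      p95
daily (use days only), mg       149.76   43.02   324.51   575.82
weekly (daily average), mg       42.41   11.14   110.95   171.49
monthly (daily average), mg      39.23   18.52   101.92   140.60
days of consumption per month     7.99    6.00    19.00    23.65
```

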