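# fgaps — the financing-gaps framework for health aid allocation

`fgaps` implements a forward-looking, goal-oriented framework for allocating
development assistance for health (DAH) across countries. Instead of ranking
countries by income alone — which penalises economic growth and misses
focus-area shortfalls — the framework compares three financing trajectories
per country through a goal's target year:

- **Need (N)** — the cost of moving a country from its *expected* mortality
  trend onto the trajectory required to meet an international health goal,
  costed with marginal cost-per-life-saved estimates;
- **Expected spending (ES)** — the domestic government spending on the focus
  area forecast from past behaviour;
- **Potential spending (PS)** — the country's ability to pay: the spending of
  the best-performing peers at the same GDP per capita, estimated as a data
  envelopment analysis (DEA) frontier.

Donor funds are then allocated by

```
DAH = α [ (N − PS) + β (PS − ES) ]
```

where `N − PS` is **Gap A** (the shortfall beyond what the country could fund
itself), `PS − ES` is **Gap B** (unrealised domestic spending potential), α is
the share of the gap the donor funds (or is solved from a fixed budget), and
β controls spending incentives: β = 1 reduces the rule to α[N − ES], β = 0 to
α[N − PS] (funding independent of expected spending), and β < 0 actively
rewards domestic investment.

The package ships a complete child-health case-study pipeline driven by the
SDG target of 25 under-five deaths per 1000 live births by 2030 and the
published cost-per-child-life-saved schedule ($4205 / $6496 / $10 016 for
low / lower-middle / upper-middle income countries), plus a synthetic-panel
generator with known generating parameters so every stage is testable by
recovery without external data. It is aimed at health-financing analysts and
donor-strategy teams who want a transparent, reproducible starting point for
allocation discussions.

## The pipeline

| stage | method |
|---|---|
| `fit-mortality` | pooled OLS of ln(U5MR) on ln GDP, ln GDP pc, maternal education, ln(1+DAH pc), ln(1+GHE-S pc) and a linear time trend |
| `forecast` | expected trend: exponentiated prediction with forecast GDP/education and health spending frozen at base-year values |
| `need` | constant annual rate of reduction ARR = 1 − (target/baseline)^(1/T); lives = Δrate/1000 × births; N = lives × unit cost |
| `expected-spend` | child-health share ~ ln GHE-S pc + ln GDP pc (OLS, clipped to [0,1]), applied to GHE-S forecasts |
| `potential-spend` | output-oriented VRS DEA of GHE-S pc on GDP pc; frontier evaluated at forecast GDP |
| `gaps`, `allocate`, `rank` | Gap A/B decomposition, the α/β rule or budget split, rankings by GDP pc, total gap, Gap A or U5MR |

## Worked example

```bash
fgaps simulate --n-countries 30 --seed 7 --out panel.csv \
      --truth-out truth.csv --subaccounts-out subaccounts.csv
fgaps run-all --panel panel.csv --subaccounts subaccounts.csv \
      --seed 7 --alpha 0.1 --out-dir case_study
```

`case_study/top_need.csv` then starts (synthetic countries, constant USD):

```
country_id  need_usd   es_usd   ps_usd  gap_a_pct_of_need  gap_b_pct_of_potential
      C026  1.93e+09 5.32e+08 5.21e+08               72.9                   -2.07
      C018  9.85e+08 3.67e+08 4.77e+08               51.6                    23.0
      C005  8.61e+08 3.52e+08 8.25e+08               4.18                    57.4
```

C026 needs $1.9 billion to reach the 2030 target; 72.9% of that need lies
beyond what it could spend at full potential (Gap A), and its expected
spending already exceeds its potential (negative Gap B) — so under β = 0 it
is the top aid recipient. With α = 0.1 the allocation stage funds 10% of each
positive Gap A (`alloc.csv`):

```
country_id  alpha  beta  raw_term  dah_usd  clipped
      C026    0.1     0  1.41e+08 1.41e+08    False
      C018    0.1     0  5.08e+07 5.08e+07    False
```

Countries whose potential spending covers their need get a negative raw term,
floored at zero. `ranks_*.csv` contrast orderings by income, mortality and
the gaps, and `manifest.json` records config, seed and input checksums.

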