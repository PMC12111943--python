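# savrcast

Forecasting the surgical burden of degenerative aortic stenosis from
population aging. `savrcast` implements a complete, tested pipeline for
a question hospital planners face: given municipality-level census
panels for a referral region and a surgical registry of aortic valve
replacements (SAVR), how many operations should the centre expect per
decade as the population ages?

The pipeline, stage by stage:

1. **Census panels** (`savrcast.census`) — validated municipality x
   census-wave tables of age-band counts (0–14, 15–64, ≥65, optionally
   ≥75 and by sex), with CSV I/O, regional aggregation and pyramid
   summaries.
2. **Aging and longevity indices** (`savrcast.indices`) —
   AI = 100·P₆₅₊/P₀₋₁₄ and LI = 100·P₇₅₊/P₆₅₊ per municipality and
   year, with per-year median/range summaries and a Kruskal–Wallis
   omnibus test plus Dunn's pairwise mean-rank z-tests
   (Bonferroni-adjusted) for shifts across census years.
3. **Geometric growth** (`savrcast.growth`) — constant compound growth
   P_t = P₀(1 + r/100)^t: rate estimation between waves,
   r = 100·((P_end/P_start)^{1/t} − 1), projection, and doubling time
   ln 2 / ln(1 + r/100).
4. **Scenario projections** (`savrcast.scenarios`) — two-phase
   (decade-by-decade) projection under a *decreasing* scenario, where
   the observed inter-decade slow-down Δ (percentage points per decade)
   applies from the first projected decade, and a *stagnation* scenario,
   where the first decade keeps the last observed rate and the
   decrement starts in the second.
5. **Demand estimation** (`savrcast.demand`) — the decade
   surgery-to-population ratio π = 100·S/P₆₅₊(end of decade) applied to
   projected elderly populations, with decade and per-year increments
   over the reference decade.
6. **Synthetic data** (`savrcast.synthetic`) — a seeded generator of
   realistic municipality panels (log-normal sizes, per-municipality
   growth noise, drifting age structure) and binomial surgical
   registries, so every stage is testable end to end.
7. **Orchestration** (`savrcast.pipeline`, `savrcast.cli`) — a
   `savrcast` command with `validate`, `indices`, `project`, `demand`,
   `generate`, `reference-run` and `run` verbs.

## Worked example

The packaged reference run projects the Lisbon tertiary-centre referral
area (41 municipalities, Portuguese censuses 2001/2011/2021) from its
published region-level figures: 2 319 319 residents in 2021, 535 894 of
them ≥65; observed rates 0.19 %/yr (total) and 1.40 %/yr (≥65) for
2011–2021, with inter-decade decrements of 0.30 and 0.29 points; and
2 424 SAVR in patients ≥65 during 2011–2021.

```sh
savrcast reference-run
```

prints (abridged):

```json
{
  "growth": {
    "doubling_time_years_65_plus": 49.8562834267127,
    "doubling_time_years_reported": 50,
    "pop_65_plus_2071": 1073932
  },
  "scenarios": { "table": [
    {"scenario": "decreasing", "stratum": "total",       "2021": 2319319, "2031": 2293932, "2041": 2201598},
    {"scenario": "decreasing", "stratum": "age_65_plus", "2021": 535894,  "2031": 598439,  "2041": 649362},
    {"scenario": "stagnation", "stratum": "total",       "2021": 2319319, "2031": 2363765, "2041": 2337892},
    {"scenario": "stagnation", "stratum": "age_65_plus", "2021": 535894,  "2031": 615827,  "2041": 687701}
  ]},
  "demand": {
    "prevalence_by_decade_pct": {"2001-2011": 0.33, "2011-2021": 0.45},
    "by_scenario": [
      {"scenario": "decreasing", "projected_surgeries": 2922, "decade_increase": 498, "per_year_increase_exact": 49.8},
      {"scenario": "stagnation", "projected_surgeries": 3095, "decade_increase": 671, "per_year_increase_exact": 67.1}
    ]
  }
}
```

Reading: at a constant 1.40 %/yr the elderly population doubles in
about 50 years, passing one million by 2071. By 2041 it reaches
~649 000 (decreasing scenario) to ~688 000 (stagnation). Applying the
latest decade ratio of 0.45 surgeries per 100 elderly, the centre
should plan for roughly 2 920–3 100 SAVR in 2031–2041 — an extra
~50–67 operations per year over the 2011–2021 workload.

The same chain runs on your own data:

```sh
savrcast generate --seed 7 --out-dir data          # or bring your own CSVs
savrcast demand data/census.csv data/registry.csv --out-dir report
```

`report/` then holds tidy index tables, the scenario table, the demand
table and a versioned `summary.json`.

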