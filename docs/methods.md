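# Methods

## The model

`savrcast` chains three deterministic models and one statistical test.

**Geometric growth.** Between census waves, populations are assumed to
grow at a constant annual compound rate, P_t = P₀(1 + r/100)^t, with r
in percent per year. This is the standard inter-censal assumption when
only wave totals are available; it implies the observed rate is
r = 100·((P_end/P_start)^{1/t} − 1) and the doubling time is
ln 2 / ln(1 + r/100). No cohort-component structure, migration or
mortality is modelled: the projection is a pure trend extrapolation,
appropriate over one to two decades and increasingly speculative beyond.

**Two-phase scenarios.** Projection from the last census year proceeds
decade by decade. A scenario is (base rate, per-decade decrement Δ,
number of phases, and whether the decrement already applies in the
first phase). Δ is an *absolute* percentage-point subtraction, not a
proportional scaling, and phase rates may go negative (decline). The
two presets bracket plausible futures:

* *decreasing* — the slow-down observed between the last two censuses
  continues, so phase rates are base−Δ, base−2Δ, …;
* *stagnation* — the first projected decade keeps the observed rate and
  the decrement starts in the second: base, base−Δ, …

A strictly-constant-rate variant is Δ = 0. Chained projections never
round intermediates; whole-person rounding happens once, in the
reporting layer (`reporting.py`), which also fixes the conventions of
2-decimal rates and prevalences and 1-decimal indices.

**Prevalence-based demand.** The decade "prevalence" is the
decade-cumulative SAVR count in patients ≥65 divided by the
*end-of-decade* ≥65 census population (×100). It is a
surgery-to-population ratio — a utilization rate, not a point
prevalence of disease; the name follows field usage. The latest
observed ratio is applied unchanged to each projected elderly
population, which assumes stable referral behaviour, surgical
indication thresholds and treatment mix over the horizon (in particular
no shift to transcatheter implantation). The denominator-year choice is
a genuine design decision: the end-of-decade census is the only wave
both decades possess on a consistent basis, and it reproduces the
observed ratios of the motivating region.

**Index comparison.** Aging (100·P₆₅₊/P₀₋₁₄) and longevity
(100·P₇₅₊/P₆₅₊) indices are computed per municipality and wave; both
are reported per 100 (the longevity index's verbal definition is
sometimes given as a bare ratio, but published values are plainly
percentages, so ×100 is applied always). Distribution shifts across
waves are tested with the tie-corrected Kruskal–Wallis H over the
per-year groups of municipality values, then Dunn's pairwise z-tests on
mean ranks, z = (R̄_a − R̄_b)/σ with
σ² = (N(N+1)/12 − Σ(t³−t)/(12(N−1)))·(1/n_a + 1/n_b), two-sided normal
p-values multiplied by the number of pairs and capped at 1 (Bonferroni).
The large-sample normal approximation is used; with ~41 values per
group it is accurate. When every pooled observation is identical the
omnibus is reported as H = 0, p = 1 (no evidence of shift) rather than
an error. Summaries report the median with a min–max envelope by
default; an interquartile option exists because "median (low–high)"
reports are ambiguous between the two.

## Tunable parameters

| parameter | units | default | why |
|---|---|---|---|
| phase_length | years | 10 | census-decade cadence |
| n_phases | decades | 2 | a 20-year planning horizon |
| decrement Δ | %-points/decade | observed slow-down | last two inter-censal rates |
| prevalence policy | — | latest decade | most recent utilization regime |
| per-year rounding | — | exact (+nearest/ceil) | ceil is the conservative capacity floor |

## The synthetic generator

`SyntheticConfig` defaults describe a region like the motivating one:
41 municipalities over waves 2001/2011/2021; log-normal base sizes
(log-mean 10, log-sd 1.1 ⇒ median ≈22 k with a dominant-city tail, so a
few municipalities drive regional aggregates); total population growing
0.49 %/yr and the ≥65 population 1.69 %/yr on average with 0.6-point
municipality-level noise; 2001 age structure 16 % aged 0–14 and 17 %
≥65, of whom 42.6 % are ≥75; a log-normal municipality dispersion of
baseline shares (sd 0.12) so baseline aging indices span a realistic
range rather than collapsing to a point; the 0–14 share falling 1.5
points and the ≥75-of-≥65 share rising 3.3 points per decade; and a
decade surgery ratio of 0.45 %. Band counts are rounded with the
residual assigned to 15–64, so the partition invariant holds exactly;
registries draw surgeries ~ Binomial(end-of-decade regional P₆₅₊,
π/100). One seed determines everything.

What it does *not* emulate: spatial correlation between neighbouring
municipalities, migration flows between them, sex structure (synthetic
records are all-sex), boundary or classification changes between
censuses, and any feedback from healthcare supply to recorded
surgeries. Passing tests on synthetic panels therefore validate the
*machinery* (estimators, projections, tests, I/O) under the model's own
assumptions, not the assumptions themselves against real data.

## Numerical choices and degenerate inputs

* Counts are exact integers; parsing accepts US-style thousands
  separators only, and decimal values are rejected rather than rounded.
* An index with a zero denominator is an explicit undefined-cell flag,
  never infinity, and undefined cells are carried, not dropped.
* Rates are exchanged in percent everywhere; conversion to
  multiplicative factors happens once inside `growth`.
* `doubling_time` refuses non-positive rates (no doubling exists).
* Validation is within-record: a panel whose sex strata disagree with
  an independently published all-sex total is *not* "fixed" — source
  inconsistencies are preserved, since cross-stratum reconciliation
  would silently alter source data.

## Problem sizes

The test suite validates the statistical machinery at the study's own
scale: 200 synthetic 41-municipality panels for the year-trend power
check and growth-rate recovery, 500 binomial replicates at a regional
elderly population of 5×10⁵ for prevalence recovery, and 1 000
randomized small panels for round-trip/partition invariants. The whole
suite runs in a few seconds on one CPU.

## Known limitations

* Trend extrapolation compounds: by 2071 the constant-rate elderly
  projection is indicative only (the package reports it as a bound
  check, not a forecast).
* Published region-level rates are printed to 2 decimals; projections
  chained from them differ from projections chained from unrounded
  populations by up to ~0.2 % over two decades. Comparisons against
  published projected populations therefore use a ±0.5 % band.
* The demand estimator is linear in the elderly population and blind to
  age composition *within* the ≥65 group, although the longevity index
  shows that composition is itself shifting; a rising ≥75 share would,
  if anything, raise true demand per capita.
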