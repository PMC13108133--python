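# Methods

## Model structure

The simulator is an expected-value cohort model of drug purchasing costs
only: no disease-related cost offsets, no health outcomes, no patient
mortality or loss to follow-up after treatment, no age structure. Every
quantity is deterministic; fractional patients are allowed.

**Patient flow.** Over a horizon of `T` years (default 25), patients
initiating therapy in year `t` are

- a backlog component: the prevalent pool `prev = prevalence_rate ×
  population × uptake`, treated in equal portions `prev/m` in years
  `0..m−1` (`m = backlog_spread_years`, default 1 — the extreme case in
  which the whole waiting population is treated at launch);
- an incident component `inc₀ × (1+g)^t`, where `inc₀` is the incidence
  rate applied to its basis population (total population, or yearly
  births for congenital disease) and `g` is a demographic growth factor
  (default 0, plausibly up to ±2%/yr).

A consistency warning (not an error) fires when `prevalence_rate`
deviates more than 10% from `incidence_rate × disease_duration`, since
for a stationary disease the two should agree.

**Payment schemes.** Upfront payment books the full price `P` in the
treatment year. An annuity-based scheme books the annuity due

    A = i·P / (1 − (1+i)^−n) · 1/(1+i),     A = P/n  for i = 0

at the beginning of each of the `n` years starting with the treatment
year. Beginning-of-period timing is what makes a one-payment scheme
collapse exactly to upfront payment (`A = P` for `n = 1`), which the code
enforces algebraically rather than through the (then ill-conditioned)
formula. The yearly budget impact under either scheme is the
superposition of all cohorts' payments due that year.

**Discounting.** Streams are built nominal, optionally inflated at a
constant rate (default 0, i.e. real terms — no inflation rate is
anchored anywhere, so none is assumed), then discounted at the social
rate of time preference `r` (default 3%) with year 0 undiscounted and
factor `(1+r)^−t` thereafter. Stream objects carry their basis
(`nominal`/`discounted`) and discounting a discounted stream raises, so
double discounting cannot happen silently.

**Horizon truncation.** Annuities owed by late cohorts fall partly
beyond year `T`. The payer's budget perspective (`window_only`, the
default) drops those payments from the stream; `full_ledger` extends the
stream by `n−1` years so every contracted payment appears. The choice
matters for the NPV cost-equivalence ratio: under `full_ledger` every
patient's annuity NPV at `i = r` equals `P` exactly, so the ratio is
identically 1 at `i = r` and the break-even bond rate equals `r`; under
`window_only` truncation slightly favors the annuity scheme.

## The four conditions

1. Discounted upfront peak must exceed the yearly cap `BI_max` while the
   discounted annuity peak stays within it. The cap is a fixed yearly
   amount and is not discounted. This is the only condition expressed in
   absolute currency, so it is the only one sensitive to the reference
   population scale (below).
2. (a) `NPV(BI_A, r)/NPV(BI_U, r) ≤ 1`; (b) `max BI_A,t / max BI_U,t ≤ 1`
   on discounted streams. Ratios of exactly 1 pass ("no greater than"),
   implemented with a 1e−9 relative tolerance.
3. Manufacturer compensation. The primary metric reports the NPV of the
   schedule at the bond rate over the principal — equal to 1 by
   construction of the annuity due; it is computed, not assigned, and
   serves as an audit that the schedule is priced correctly. The
   secondary metric `n·A/P` reports the undiscounted financing premium
   the payer concedes. The quantitative definition behind published
   per-scheme "condition 3" figures for this model class could not be
   pinned down, so both explicit metrics are exposed instead.
4. `n ≤ floor(durability_years)`: a payer should not still be paying for
   an effect that is no longer credibly present. A durability of 2.5
   years therefore caps annuities at 2.

## Parameters and defaults

| parameter | units | default | why |
|---|---|---|---|
| horizon `T` | years | 25 | one budget generation |
| social discount rate `r` | /yr | 0.03 | standard public-expenditure rate |
| inflation | /yr | 0 | real terms; no rate to anchor |
| health-impact bond rate | /yr | 0.03 | top of the 1–3% government range |
| corporate bond rate | /yr | 0.10 | top of the 8–10% private range |
| maturities `n` | years | 5, 10, 15 | conventional bond maturities |
| backlog spread `m` | years | 1 | extreme all-at-launch case; swept 1–5 |
| population / births | persons | 11.5M / 120k | Belgium-like reference |
| uptake | fraction | 1.0 | fold partial uptake into the rates |

The reference population is a modelling choice, not data: all condition
ratios (2a, 2b, 3) are invariant under joint scaling of population and
births, so it only anchors absolute euro figures against `BI_max`.
Preset caps (€250M/yr and €10M/yr) and prices (€1M, €350k) are the
illustrative values of the two preset indications.

## Scenario presets

`lca` — prevalence-dominant: prevalence 1/10,700 of the population,
incidence 1/750,000 newborns, duration ~70 years, durability 75 years.
`dlbcl` — incidence-dominant: incidence 2.5/100,000 of the population,
duration 0.5 years (hence prevalence 1.25/100,000), durability 2.5
years. Both: 25-year horizon, 3% social discounting, the six-scheme
financing grid.

With these presets the model reproduces the qualitative pattern the
conditions are designed to capture: for the prevalence-dominant preset,
health-impact-bond schemes satisfy all four conditions (peak yearly
budget impact falls to 8–24% of the upfront peak across the six
schemes), while corporate bonds at 10% fail cost-equivalence; for the
incidence-dominant preset the annuity stream itself stays above the cap
(condition 1 fails) and the 2.5-year durability rules out every 5–15
year maturity (condition 4 fails). One divergence is documented: the
5-year health-impact scheme also satisfies all four conditions here,
because under the explicit NPV-identity metric condition 3 cannot fail;
analyses that grade manufacturer compensation on an unstated threshold
may judge that row marginal.

## Numerical choices

- Annuity denominator `1 − (1+i)^−n` is computed as
  `−expm1(−n·log1p(i))`, which stays accurate for rates down to the
  floating-point floor (naive evaluation loses ~9 digits at i ≈ 1e−9);
  rates that underflow entirely fall back to the exact `P/n` limit.
- Currency is kept at full float precision internally and rounded only
  for display (reports format ratios to 2 decimals).
- The annuity window sum is a convolution of the initiation vector with
  a length-`n` box; a brute-force per-(patient, payment-year) ledger is
  kept in the test suite as an independent oracle.
- Dominance classification breaks the `prev/inc = 1` tie toward
  incidence-dominant.
- Degenerate inputs raise rather than guess: zero upfront NPV or peak
  (ratio undefined), backlog spread longer than the horizon, empty or
  unordered sweep grids, discounting twice.

## Known limitations

- Condition 1 — and only condition 1 — depends on the invented absolute
  population scale. In the prevalence-dominant preset, spreading the
  backlog over 5 years drops the upfront peak itself below the €250M cap,
  flipping condition 1 even though every scale-free verdict is unchanged;
  conclusions about condition 1 should be read against `BI_max` per
  treated patient, not the absolute preset cap.
- Constant annuities only: no outcome-based rebates, no payment
  reduction on early death or loss to follow-up, no renegotiation.
- Yearly granularity; payments and treatments fall on year boundaries.
- The synthetic patient flow is smooth and deterministic. Real uptake is
  lumpy and uncertain; passing tests demonstrate the accounting and the
  condition logic, not epidemiological forecasting skill.
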