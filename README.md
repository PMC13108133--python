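# abpsim

A deterministic budget-impact simulator for funding **one-time advanced
therapies** (gene and cell therapies) either with a single upfront
payment or with **annuity-based payments (ABP)** — paying the negotiated
price *P* in *n* equal yearly installments financed at a bond rate *i* —
and screening each financing scheme against four feasibility conditions
that both the healthcare payer and the manufacturer must accept.

It is written for health-economics and HTA analysts exploring managed
entry agreements: when does spreading a €1M-per-patient price actually
relieve the yearly budget, and when is it just a more expensive way to
pay?

## Model

Patients initiating therapy in year *t* over a horizon *T* (default 25
years) are the sum of a prevalent **backlog** `prev`, treated in equal
portions over the first *m* years, and an **incident** flow
`inc·(1+g)^t`. A disease is *prevalence-dominant* when `prev/inc > 1`
(e.g. an inherited retinal dystrophy with a lifelong backlog) and
*incidence-dominant* otherwise (e.g. an aggressive lymphoma with no
backlog).

Each patient treated in year *s* either costs *P* upfront in year *s*,
or owes the **annuity due**

```
A = i·P / (1 − (1+i)^−n) · 1/(1+i)        (A = P/n as i → 0)
```

at the beginning of each of years *s, s+1, …, s+n−1*. Yearly budget
impacts `BI_U,t` and `BI_A,t` follow by superposition over cohorts, and
are discounted at a social rate of time preference *r* (default 3%).

The four conditions:

1. **Budget-cap relief** — the discounted upfront stream must breach the
   payer's yearly cap `BI_max` in some year while the annuity stream
   stays within it every year.
2. **Cost-equivalence** — (2a) `NPV(BI_A, r) ≤ NPV(BI_U, r)` over the
   horizon and (2b) `max_t BI_A,t ≤ max_t BI_U,t` on discounted streams.
3. **Manufacturer compensation** — the schedule's NPV at the bond rate
   equals the principal (the defining identity of the annuity due),
   reported alongside the undiscounted premium `n·A/P` the payer concedes.
4. **Durability-limited spread** — *n* must not exceed the credible
   durability of the therapy's effect, in whole years.

Two presets encode illustrative indications: `lca` (prevalence-dominant:
prevalence 1/10,700, incidence 1/750,000 newborns, price €1M, cap
€250M/yr) and `dlbcl` (incidence-dominant: incidence 2.5/100,000, price
€350k, cap €10M/yr, durability ≈ 2.5 years).

## Worked example

```
$ abpsim run --preset lca
```

(selected columns)

```
    bond_type  bond_rate  maturity_years  c1_pass  c2a_ratio  c2b_ratio  c3_nominal_sum  c4_pass  overall_feasible
health_impact       0.03               5     True   0.999854   0.211995        1.059974     True              True
health_impact       0.03              10     True   0.999664   0.113816        1.138160     True              True
health_impact       0.03              15     True   0.999465   0.081327        1.219902     True              True
    corporate       0.10               5    False   1.131070   0.239816        1.199079     True             False
    corporate       0.10              10     True   1.299471   0.147950        1.479504     True             False
    corporate       0.10              15     True   1.468860   0.119522        1.792824     True             False
```

Reading the first row: financing the €1M therapy with a 3%
health-impact bond over 5 years means an annuity of €211,995 per
patient, so the peak yearly budget impact falls to 21.2% of the upfront
peak (`c2b_ratio`) — the ~€1.07bn year-0 bill for the treated backlog
becomes ~€228M, inside the €250M cap (`c1_pass`). The scheme is
NPV-cost-equivalent for the payer (`c2a_ratio ≤ 1`, since the bond rate
equals the social discount rate) while the payer nominally concedes a
6.0% financing premium to the manufacturer (`c3_nominal_sum`). Corporate
bonds at 10% fail cost-equivalence (`c2a_ratio > 1`): the spread payment
is then strictly more expensive than paying upfront.

The break-even bond rate — the largest *i* at which cost-equivalence
still holds under full-ledger accounting — is the social discount rate:

```
$ abpsim threshold --preset lca --truncation full_ledger
0.03
```

Other entry points: `abpsim presets` (list/dump scenario YAML),
`abpsim sweep --preset lca --axis backlog_spread_years=1,2,3,4,5` for
sensitivity grids, and the library API (`abpsim.run_preset`,
`abpsim.evaluate_all`, `abpsim.stream_table`, …).

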