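# Incidence-dominant preset: diffuse large B-cell lymphoma treated by
# one-time CAR-T therapy. Essentially no backlog (patients die quickly
# untreated); a steady flow of new relapsed cases each year; effect
# durability highly uncertain beyond ~30 months.
name: dlbcl
price: 350000.0           # EUR per patient
durability_years: 2.5     # credible durability of effect
truncation: window_only
epidemiology:
  population_size: 11500000
  births_per_year: 120000
  prevalence_rate: 1.25e-05   # 1.25/100,000 of the population
  incidence_rate: 2.5e-05     # 2.5/100,000 of the population per year
  incidence_basis: population
  growth_rate: 0.0
  backlog_spread_years: 1
  disease_duration_years: 0.5
  uptake_fraction: 1.0
economics:
  budget_cap: 10000000.0    # EUR per year, BI_max
  social_discount_rate: 0.03
  inflation_rate: 0.0
  horizon_years: 25
schemes:
  - {modality: annuity, bond_type: health_impact, bond_rate: 0.03, n_payments: 5}
  - {modality: annuity, bond_type: health_impact, bond_rate: 0.03, n_payments: 10}
  - {modality: annuity, bond_type: health_impact, bond_rate: 0.03, n_payments: 15}
  - {modality: annuity, bond_type: corporate, bond_rate: 0.10, n_payments: 5}
  - {modality: annuity, bond_type: corporate, bond_rate: 0.10, n_payments: 10}
  - {modality: annuity, bond_type: corporate, bond_rate: 0.10, n_payments: 15}
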