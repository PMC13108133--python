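# Prevalence-dominant preset: Leber's congenital amaurosis (RPE65) treated
# by one-time gene therapy. Large backlog of existing patients, tiny yearly
# incidence among newborns, lifelong disease.
name: lca
price: 1000000.0          # EUR per patient
durability_years: 75.0    # envisaged lifetime benefit of the therapy
truncation: window_only
epidemiology:
  population_size: 11500000
  births_per_year: 120000
  prevalence_rate: 9.345794392523364e-05   # 1/10,700 of the population
  incidence_rate: 1.3333333333333334e-06   # 1/750,000 newborns
  incidence_basis: births
  growth_rate: 0.0
  backlog_spread_years: 1
  disease_duration_years: 70.0
  uptake_fraction: 1.0
economics:
  budget_cap: 250000000.0   # EUR per year, BI_max
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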