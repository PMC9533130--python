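# Base-case model inputs for six first-line ALK inhibitors in advanced
# ALK-positive NSCLC (Chinese healthcare-system perspective, 2021 USD).
# All values appear verbatim in the units they were published in (USD,
# per day or per 8-week cycle); no hidden unit conversions.
#
# Ranges are the one-way sensitivity bounds: hazard ratios and health-state
# utilities span their published 95% CIs, drug acquisition costs span
# 30-120% of baseline, all other costs and the AE disutilities span +/-20%,
# the discount rate spans 0-8%.  `dist` is the probabilistic-sensitivity
# distribution family; parameters without one (the base Weibull curves and
# the discount rate) are held fixed in the Monte Carlo analysis.
#
# Note: one published sensitivity statement quotes the alectinib daily cost
# as 84.33; the input table prints 84.32, which is used here.

model:
  cycle_length_days: 56        # 8-week cycle, matching routine follow-up
  horizon_years: 10            # lifetime horizon; cohort extinct well before
  discount_rate_annual: {value: 0.05, range: [0.0, 0.08]}
  wtp_per_qaly: 37654          # 3x China's 2021 per-capita GDP, USD/QALY
  cny_per_usd: 6.4515          # metadata only; the model operates in USD

base_survival:
  time_unit: cycle             # lambda/gamma act on the 8-week cycle grid
  os:  {scale: 0.02092, shape: 1.25579}
  pfs: {scale: 0.08242, shape: 1.21862}

strategies:
  - name: ensartinib
    hr_os:  {point: 0.88, ci: [0.45, 1.73], dist: normal}
    hr_pfs: {point: 0.48, ci: [0.20, 1.21], dist: normal}
    drug_cost_per_day: {value: 59.29, range: [17.79, 71.15], dist: gamma}
    ae_cost_once:      {value: 798.62, range: [638.90, 958.35], dist: gamma}
    ae_disutility:     {value: 0.046, range: [0.037, 0.055], dist: beta}
  - name: crizotinib
    reference: true
    drug_cost_per_day: {value: 70.93, range: [21.28, 85.12], dist: gamma}
    ae_cost_once:      {value: 566.40, range: [453.12, 679.68], dist: gamma}
    ae_disutility:     {value: 0.033, range: [0.026, 0.039], dist: beta}
  - name: ceritinib
    hr_os:  {point: 0.90, ci: [0.44, 1.82], dist: normal}
    hr_pfs: {point: 1.28, ci: [0.44, 3.84], dist: normal}
    drug_cost_per_day: {value: 105.40, range: [31.62, 126.48], dist: gamma}
    ae_cost_once:      {value: 2639.42, range: [2111.53, 3167.30], dist: gamma}
    ae_disutility:     {value: 0.152, range: [0.122, 0.182], dist: beta}
  - name: alectinib
    hr_os:  {point: 0.67, ci: [0.38, 1.18], dist: normal}
    hr_pfs: {point: 0.41, ci: [0.21, 0.77], dist: normal}
    drug_cost_per_day: {value: 84.32, range: [25.30, 101.19], dist: gamma}
    ae_cost_once:      {value: 345.50, range: [276.40, 414.60], dist: gamma}
    ae_disutility:     {value: 0.020, range: [0.016, 0.024], dist: beta}
  - name: brigatinib
    hr_os:  {point: 0.92, ci: [0.49, 1.74], dist: normal}
    hr_pfs: {point: 0.49, ci: [0.20, 1.23], dist: normal}
    drug_cost_per_day: {value: 305.30, range: [91.59, 366.36], dist: gamma}
    ae_cost_once:      {value: 724.99, range: [579.99, 869.99], dist: gamma}
    ae_disutility:     {value: 0.042, range: [0.033, 0.050], dist: beta}
  - name: lorlatinib
    hr_os:  {point: 0.72, ci: [0.36, 1.43], dist: normal}
    hr_pfs: {point: 0.28, ci: [0.11, 0.69], dist: normal}
    drug_cost_per_day: {value: 209.25, range: [62.78, 251.10], dist: gamma}
    ae_cost_once:      {value: 1200.77, range: [960.61, 1440.92], dist: gamma}
    ae_disutility:     {value: 0.069, range: [0.055, 0.083], dist: beta}

shared_costs:
  followup_per_cycle:           {value: 383.63, range: [306.91, 460.36], dist: gamma}
  subsequent_therapy_per_cycle: {value: 2277.47, range: [1821.98, 2732.96], dist: gamma}
  bsc_per_cycle:                {value: 900.00, range: [720.00, 1080.00], dist: gamma}
  palliative_terminal:          {value: 7007.47, range: [5605.98, 8408.96], dist: gamma}

utilities:
  u_pfs: {value: 0.856, range: [0.718, 0.994], dist: beta}
  u_pd:  {value: 0.768, range: [0.595, 0.941], dist: beta}

psa:
  n_iterations: 10000
  seed: 20220921

conventions:
  trace_mode: partitioned      # state occupancy read off the OS/PFS curves
  half_cycle: true             # membership averaged over cycle boundaries
  palliative_timing: once_at_death
  ae_cost_timing: once_at_entry
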