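# Methods

## Model structure

The model is a three-state cohort simulation: progression-free on
first-line treatment (PFS), progressed disease on subsequent therapy (PD),
and death. The horizon is 10 years in 8-week (56-day) cycles —
floor(10 × 365.25 / 56) = 65 cycles, recorded in every output header so
alternative roundings are auditable. By 65 cycles the modelled cohorts are
effectively extinct (reference-arm overall survival < 0.1%), so the
horizon acts as a lifetime horizon.

Two curves drive everything: Weibull overall survival (OS) and
progression-free survival (PFS) for the reference arm, S(t) = exp(−λt^γ)
with t counted in cycles. Comparators are generated by proportional
hazards — the hazard ratio (HR) from an indirect treatment comparison
multiplies λ, γ is shared. This assumes proportional hazards over the
whole horizon; no waning option is provided.

**Time unit.** λ and γ are interpreted on the cycle grid. This reading is
validated internally: it implies a reference-arm median PFS of ≈ 5.74
cycles ≈ 10.6 months and median OS ≈ 30 months, the scale actually
observed in the underlying crizotinib trial. A month-unit reading would
imply a 5.7-*month* median PFS, clinically wrong for this population. The
configuration records the unit explicitly (`base_survival.time_unit`).

**Trace modes.** The default `partitioned` mode reads occupancy off the
curves (PD = S_OS − S_PFS, floored at zero with a logged warning when the
curves cross, which happens only for extreme HR combinations). The
`state_transition` mode runs a Markov chain with the OS death hazard
applied to both alive states and progression taking the remaining PFS
exit hazard; it reproduces the partitioned alive fraction exactly by
construction and differs only where PD clamping binds. Both modes are
exercised by the tests.

## Economic accumulation

Per cycle t with discount factor d(t) = 1.05^(−t·56/365.25):

* QALYs: d(t)·[PFS(t)·(u_PFS − disutility) + PD(t)·u_PD]·(56/365.25),
  with u_PFS = 0.856, u_PD = 0.768. The per-strategy grade-III/IV
  adverse-event disutility is charged during PFS occupancy only, because
  first-line treatment continues until progression.
* Costs: PFS cycles carry drug acquisition (daily price × 56) plus routine
  follow-up ($383.63) and best supportive care ($900.00); PD cycles carry
  subsequent anticancer therapy ($2,277.47) plus follow-up and BSC.
  Adverse-event management is a one-time cost at model entry (grade-III/IV
  events concentrate early); palliative care ($7,007.47) is a one-time
  terminal cost attached to incident deaths in the cycle they occur.
* Death carries zero cost and zero utility beyond the palliative charge.

Four structural conventions are not pinned down by the published methods
and are therefore explicit switches with documented defaults:
`half_cycle` (default on: state membership averaged over adjacent cycle
boundaries), `palliative_timing` (`once_at_death` default vs
`per_final_cycle`), `ae_cost_timing` (`once_at_entry` default vs
amortized over on-treatment cycles), and `trace_mode` (above). The tests
verify that every switch moves totals by < 5%, so none of them can
explain a large discrepancy with published outputs.

The model operates natively in 2021 USD; the CNY-per-USD rate (6.4515) is
carried as metadata only. Discounting is 5%/year (range 0–8% in DSA).
Verdicts use a willingness-to-pay threshold of $37,654/QALY. For pairs
where the intervention loses QALYs but saves money, the reported ICER is
the cost per QALY *bought back* by the dearer strategy, and the pairwise
table orients each comparison with the higher-QALY arm as intervention —
the usual presentation for this drug class.

## Convention audit (why one acceptance check is red)

Running the bundled inputs reproduces the published *cost* column to
within 10% on every arm (four of six within 3%) and all five published
verdicts exactly. The published *QALY* column is a different story: the
model yields 2.17–2.86 discounted QALYs across arms where the published
table prints 0.91–1.25 — a near-constant factor of ≈ 2.3. We audited every
combination of the convention switches (none move QALYs more than a few
percent; two do not touch QALYs at all) and a continuum of structural
re-readings (curve time unit, per-cycle vs annual discounting, cycle
length): no natural combination fits both published columns at once. The
closest QALY match (month-unit curves with 5% discounting applied per
8-week cycle) would miss the cost column by ~50%. The published cost and
QALY columns are therefore mutually inconsistent with any single model of
this family built from the published inputs, and the implementation
follows the *stated* methods instead of chasing the printed QALYs. The
acceptance test that compares QALYs against the published column is left
failing, with the discrepancy spelled out in its message.

A corollary worth noting: the discounted life expectancy implied by the
published QALYs (≈ 1.2 years for crizotinib) contradicts the ≈ 30-month
median OS implied by the published Weibull parameters; our 2.17 QALYs sit
exactly where those survival curves put them.

## Sensitivity analysis

**One-way DSA.** Each uncertain parameter is set to its published low and
high bound with everything else at baseline, the full model is re-run,
and entries are ranked by ICER swing. HRs and utilities span their
published 95% CIs, ALK-TKI daily prices span 30–120% of baseline, other
costs and the disutilities ±20%, discount rate 0–8%. The base Weibull
parameters are fixed. Verdict changes at a bound are annotated.

**Threshold search.** The verdict flip is located as the sign change of
the incremental net monetary benefit (equivalent to the ICER-vs-threshold
rule, but well defined through dominance regions) by plain bisection to
relative tolerance 1e-6, after a 9-point bracket scan that rejects
non-monotone intervals with advice to grid-scan. Tests validate the root
against an independent grid-scan oracle.

**PSA.** Each distribution-tagged parameter gets a moment-matched
distribution with SD = (high − low)/3.92, i.e. the published range is
treated as a 95% interval. That is exact for the HR confidence intervals;
for the ±20% cost ranges it is a pragmatic stand-in, a known limitation.
HRs are drawn Normal per the published analysis (truncated at zero by
redraw; a log-normal switch exists for robustness checks), costs Gamma,
utilities and disutilities Beta, all independently — no correlation
structure was published. Draws that would break the accumulators
(on-treatment utility below zero) are redrawn and counted; the utilities
are otherwise left unconstrained, so u_PD > u_PFS can occur by chance, as
it would under the published independent-draw scheme. CEACs report the
fraction of draws in which each strategy has the maximal net monetary
benefit (ties broken by column order; measure-zero under continuous
draws).

Because the model is convex in the hazard ratios and the HR intervals are
wide, Monte Carlo mean outputs for HR-driven arms sit systematically above
the deterministic base case (Jensen's inequality) — this is a property of
the published distributional choices, not a bug. The PSA-mean-vs-baseline
test therefore checks the reference arm, whose drawn inputs enter
linearly.

## Synthetic data

`simulate_ipd` draws event times from a known Weibull by inverse CDF and
censors them with an independent exponential time whose rate is calibrated
by bisection (on the realised sample) so the overall censored fraction —
administrative censoring at end of follow-up included — hits the target.
It emulates the sample sizes and ~20% censoring typical of the underlying
first-line trials. It does *not* emulate treatment crossover, informative
censoring, or the administrative-heavy censoring pattern of real trials,
so passing recovery tests show correctness of the reconstruction/fitting
machinery, not robustness to those real-data features.

`km_from_ipd` produces the digitised-curve artifact (product-limit steps
via lifelines, number-at-risk on a grid). `reconstruct_ipd` inverts it
with interval allocation: within each risk-table interval the number
censored is iterated until the implied number at risk matches the
published one, censoring times are spread uniformly, and event counts
follow the digitised steps; after the last risk entry survivors are
censored at the last coordinate. Parameter recovery through the full
simulate → digitise → reconstruct → refit loop is within 10% relative
error at n = 2,000 (fixed seed), and the reconstructed curve tracks the
input curve to < 0.02 at n = 200.

Parametric fitting is maximum likelihood under right censoring via
lifelines' univariate fitters (exponential, Weibull, log-normal,
log-logistic), with the Weibull converted to the rate parameterisation
(λ = scale^−shape). Family selection minimises AIC, ties broken toward
fewer parameters, then lexically; BIC (k·ln n − 2ℓ, n = records) is
reported alongside.

## Problem sizes and numerical choices

Default test and analysis sizes, chosen to keep every stage desk-scale:
65-cycle traces (exact, vectorised); 1,000-draw PSA in the end-to-end test
and 500 draws in unit tests (the CLI default is the configured 10,000);
2,000 subjects for parameter-recovery checks; 100,000 draws for
distribution round-trip checks. Trace validation tolerances are 1e-9 on
row conservation; the telescoping identity between per-cycle transition
probabilities and the survival curve holds to machine precision and is
asserted at 1e-15. Bisection tolerances: 1e-6 relative (threshold search),
200 iterations (censoring-rate calibration). Degenerate inputs are
handled explicitly: zero horizon (entry costs only), zero discount
(factor ≡ 1), HR = 1 (trace identical to reference), all-censored KM
artifacts, single-candidate family selection.

## Known limitations

* Proportional hazards over the full horizon for all comparators; no
  treatment-switching or waning adjustment (the known crossover in one
  underlying trial is acknowledged, not modelled).
* Normal (not log-normal) HR draws by default, matching the published
  distributional choices.
* Independent parameter draws; no correlation between OS and PFS effects
  of the same drug, which likely understates joint uncertainty.
* Subsequent-therapy cost charged for every PD cycle with no stopping
  rule; second-line treatment is a lumped cost, not a sequencing model.
* The utility-decrement inputs are consumed as published per-strategy
  values; the frequency-weighting arithmetic that produced them is out of
  scope (per-event frequencies were not published).
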