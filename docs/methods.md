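# Methods

## Study structure and conventions

The analysis compares three care strategies for hypertensive patients in a
public health system: conventional care (pre-PC, 2006–2008), the year of a
pharmacist-led pharmaceutical-care program (PC, 2009), and the years after
discharge (post-PC, 2010–2012). Costs are kept in 2015 USD throughout
(`costing.adjust_and_convert` applies a single inflation factor and the
BRL 3.87/USD rate at ingestion only; formatting to 2 decimals never feeds
back into computation). Effects are proportions in [0, 1], never percents:
the period CER 364.65 is 198.37 / 0.544.

Period-level effectiveness values (0.544, 0.982, 0.93) are inputs, not means
of the yearly proportions — they were measured on the subset of patients
observed in all three periods, a subset that cannot be reconstructed from the
yearly values. `cea.period_aggregate` therefore takes the period effect as an
explicit argument and falls back to the mean of yearly proportions only when
none is given. Period cost is the unweighted mean of the yearly per-patient
means.

The intervention cost of US\$ 210.80 per patient-year enters as a single
configurable number added to the 2009 summary (`costing.add_pc_program_cost`,
guarded against double application); the underlying staffing/materials
worksheet is out of scope. The acceptability threshold is the stated
US\$ 30,721.28 (3 × GDP per capita 10,240.43); the recomputation
3 × 10,240.43 = 30,721.29 differs in the last digit, so the constructor
treats a mismatch beyond US\$ 0.05 as a warning and uses the stated value.

## Costing model

Unit costs follow public-health-system accounting: a consultation carries the
health unit's base cost (annual expenditure / annual appointments); an
emergency visit adds a fixed urgent-care bundle; a specialised visit sums a
per-visit category with annual exams spread over 3 visits and biennial exams
over 6; drugs are costed per milligram; transport charges the municipal flat
fare for two trips per consultation (fare-exempt patients pay zero; the trip
multiplier is config-exposed because the source only says "to and return");
absenteeism charges 4 h per consultation at an hourly wage of 13 monthly
salaries / 1760 worked hours (11 months × 20 days × 8 h — labour-law
constants, config-exposed). Cohort aggregation uses the study's scaling rule:
the mean over patients with complete cost data × 104 enrolled patients
(188.89 × 104 = 19,644.56 against the printed overall 19,644.73; the
difference is rounding of the printed mean). Reported SDs use the sample
(n − 1) denominator; the source does not state its convention.

## Synthetic cohort

`cohort.generate_cohort` emulates the data the analysis needs and nothing
more: per-year totals from the truncated cost distributions below, cost
components split from the total by configurable shares (defaults: medications
0.35, primary 0.20, specialised 0.15, emergency 0.10, labs 0.08, transport
0.05, absenteeism 0.07) with multiplicative log-normal jitter (sd 0.10)
renormalised so components re-sum exactly — only totals drive the analysis,
the split merely makes records realistic; and an independent Bernoulli
controlled/uncontrolled outcome per patient-year with the year's proportion
as success probability. An optional persistence parameter (probability of
carrying last year's state forward) induces within-patient correlation for
Cochran-Q experiments; the default is zero because the source states no
correlation structure. Missingness removes a randomly chosen *suffix* of
years from each incomplete patient's cost rows (dropout), leaving exactly 51
of 104 patients complete; outcomes are untouched.

What the generator does **not** emulate: blood-pressure trajectories in mmHg,
cardiovascular events, per-component cost distributions, or any
cost–outcome dependence within a patient. Tests passing on this cohort
therefore validate the pipeline's arithmetic and calibration, not clinical
realism.

## Distributions and the PSA

Patient-level data behind the published distribution fits is unavailable, so
families and moments are taken as reported (log-logistic pre-PC, log-normal
PC, Weibull post-PC; mean/SD per year) and parameters are recovered by method
of moments:

- log-normal: σ² = ln(1 + sd²/mean²), μ = ln(mean) − σ²/2 (closed form);
- Weibull: shape k solves cv² = Γ(1+2/k)/Γ(1+1/k)² − 1 by Brent's method on
  [0.05, 500] (xtol 1e-12), scale = mean/Γ(1+1/k);
- log-logistic: with b = π/β, cv² = 2sin²b/(b·sin2b) − 1, solved for β on
  (2, 10⁷]; finite variance requires β > 2, and an unattainable cv is
  rejected rather than clipped. Scale α = mean·sin(b)/b (also the median).

Truncation to the published limits uses inverse-CDF restriction
(u ~ U(F(a), F(b)), x = F⁻¹(u)): every draw is inside the bounds and the
draw count is deterministic, which keeps fixed-seed runs bit-identical.
Outcome distributions are triangular with mode = the yearly proportion (the
source does not distinguish mean from mode) and the published min/max, capped
at 1. A helper reconstructs the outcome truncation limits from the stated
rule (25% control floor pre-PC, the period's largest relative variation
applied around each year's value, intervention year borrowing the
post-period variation); its output approximates but is not forced to match
the published limits, which the stated rule itself does not reproduce
exactly.

The Anderson–Darling statistic A² = −n − (1/n)Σ(2i−1)[ln F(x₍ᵢ₎) +
ln(1 − F(x₍ₙ₊₁₋ᵢ₎))] ranks candidate families (lower = better); CDF values
are clamped to [1e-12, 1 − 1e-12], ties within 1e-12 keep input order, and no
p-values are computed (the published ones came from software-specific
tables).

`psa.run_psa` performs 10,000 iterations by default: one cost and one outcome
draw per year, all independent (no correlation structure is stated), the PC
program cost added to intervention-year cost draws, years averaged into
period costs/effects, then period CERs, CER differences vs the baseline
period and period ICERs. Draws with ΔE = 0 leave the ICER undefined; they are
excluded from ICER summaries and counted, rather than mapped to ±∞, so
summaries stay finite.

**Consequence of moment-only fitting:** the Monte Carlo summaries reproduce
the published ones qualitatively, not numerically. At seed 42 the run gives
mean ICER_PC ≈ 466 with P(ICER_PC > 0) = 98.4% and P(post-PC CER
difference < 0) = 86.3%, against published values of 605.09, 99.9% and
92.7% — same signs, same decision, different magnitudes, as expected when
the original fitted parameters cannot be recovered from printed moments.

## Incremental net benefit

The published INB expression is written as a ratio, but every published INB
value (13,246.38 at the threshold; ≈0 at λ = ICER; 64.79 for post-PC at
λ = 210.80) satisfies the standard linear form INB = λ·ΔE − ΔC, which is what
this package implements. Sweeps evaluate the closed form on a linear
(optionally log-spaced) grid including both endpoints; the break-even λ is
computed as ΔC/ΔE, never searched.

## Numerical and edge-case choices

- CER at zero effect and Cochran's Q with every row constant raise an
  undefined-result error instead of returning infinities — except that a
  matrix whose columns are all identical returns Q = 0 (perfect homogeneity
  is "no heterogeneity", not an error), which also keeps Q well defined for
  the all-ones matrix.
- ICER with ΔE = 0 is None; the comparison is then classified by cost sign.
- Dominance labels partition the plane: dominant (ΔC < 0, ΔE > 0), dominated
  (ΔC > 0, ΔE < 0), trade-off NE, trade-off SW; the origin is labelled
  trade-off NE by convention.
- Degenerate specs (sd = 0 or family "degenerate") collapse every sampler to
  the constant mean, so a degenerate PSA reproduces the deterministic point
  estimates to 1e-6 — used as an end-to-end consistency check.
- Cochran-Q significance uses the χ² 95th percentile at df = k − 1 (5.99 for
  three periods).

## Problem sizes

Unit and property tests run at 10³–10⁵ draws (3-standard-error bands for
stochastic assertions); the acceptance checks use 10,000 PSA iterations, 10⁵
truncated draws for bound checks, and a 10⁵-patient single-year cohort for
parameter recovery. The full suite completes in well under a minute.

## Known limitations

- Published period outcomes and the per-patient PC cost are taken as inputs;
  neither is derivable from other printed numbers.
- The Monte Carlo block matches the published summaries only qualitatively
  (see above); printed values that disagree with their own recomputation in
  the last digit (e.g. post-PC period ICER 42.95 vs 42.96 recomputed, INB
  −209.01 vs −209.10) are treated as source rounding, with ±0.05 USD
  tolerance in tests.
- The historical inflation series is reduced to one user-supplied factor; the
  original municipal ledger extracts are not reconstructed.
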