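# Methods

## Cohort model

The unit of analysis is the person-wave observation: waves are pooled and
treated as independent cross-sections, with no deduplication of persons
across waves. The exclusion cascade drops, in order, (1) rows with missing
age or age < 50, (2) rows missing any of SRHQ, hearing-aid use, education,
gender or country, (3) rows missing the cross-sectional calibration weight.
A row failing several criteria is counted once, at its first failing step —
the order is a declared convention, and the log reconciles exactly
(`n_input = n_retained + Σ drops`).

Outcome definitions. *Hearing loss* (standard): SRHQ ∈ {4 fair, 5 poor}.
*Sensitivity* variant: additionally counts hearing-aid users whatever their
rated hearing, so its HL-positive set is a superset of the standard one and
the standard→sensitivity prevalence comparison is one-sided by construction.
*HA eligibility*: aid user, or hearing rated less than good. The HA-use
analysis denominator is always the eligible subset, which is itself a subset
of the HL analysis sample (asserted on every pipeline run).

Region is a country → {Northern, Western, Southern, Eastern} lookup shipped
as an editable 2-column CSV (28 countries, welfare-regime style grouping);
the canonical assignment is not printed in the source material, so the
default table is explicitly overridable.

## Standardization

Stratum prevalence is Σwᵢyᵢ/Σwᵢ. Direct standardization uses the ESP 2013
five-year band weights (bundled; full-population sum of 100,000 asserted at
load, 85+ aggregated from the published 85–89/90–94/95+ rows). Bands absent
from a stratum are dropped and the standard weights renormalized over the
bands present — this keeps sparse strata computable and is exactly
equivalent to restricting the standard to the covered range; an empty
overlap yields an explicit *unavailable* flag, never an imputed zero.
Prevalences are carried as proportions and rendered as percentages (1
decimal) only at the reporting layer.

Coarse reporting groups 50–64 / 65+ / Total are standardized over the
five-year bands falling in each group. A 65–79 sensitivity scheme excludes
all records aged 80+ from estimation.

## Inequality indices

Ridit scores are cumulative-midpoint scores of the weighted education
distribution, recomputed inside every analysis stratum (and every bootstrap
replicate). The inequality line is fitted by **ordinary least squares** by
default. Share-weighted WLS is available (`weighting="shares"`), but OLS is
the default because only the unweighted fit reproduces all eight published
regional Total RIIs at one-decimal rounding; with share weights, the
strongly skewed Southern-Europe female education distribution (74.6% low)
pulls the fit toward the low-education point and yields 1.9 where 1.6 is
published. The two options agree at printed precision in the other seven
cells.

RII is ŷ(0)/ŷ(1); a non-positive ŷ(1) makes the ratio undefined (NaN), a
case that matters inside bootstrap replicates and is counted, never
silently dropped. SII is reported in percentage points. Orientation: rank 0
is the lowest-educated end, so RII > 1 and SII > 0 both encode disadvantage
of the low-educated.

## Bootstrap

Resampling unit is the person-wave record, stratified within region ×
gender so every stratum keeps its original size; the full estimation chain
is recomputed per replicate. B = 1,000 by default, 95% level. Percentile
intervals use linear interpolation of order statistics (numpy's default
quantile rule; endpoints depend on this choice, which is why it is pinned
and tested against an order-statistic oracle). BCa applies the median-bias
correction z₀ = Φ⁻¹(#{θ*<θ̂}/B) — clipped to (1/(B+1), B/(B+1)) when all
replicates fall on one side — and the jackknife acceleration
a = Σd³/(6(Σd²)^{3/2}), with leave-one-out jackknife up to n = 2,000 and a
grouped delete-d jackknife (50 random groups) above it. When z₀ = a = 0 the
adjusted levels are set to the nominal ones exactly, so BCa is bit-identical
to percentile in the no-correction case; a zero-variance jackknife falls
back to a = 0 and is flagged. Each (stratum, purpose) pair draws from its
own SHA-256-derived RNG stream off the master seed, so adding strata never
perturbs existing results.

## Synthetic data generator

The generator emulates the *structure* of the harmonized European survey:
eight region × gender cells with the published education distributions as
defaults; integer ages from a truncated geometric distribution on [50, 99]
(decay 0.96 per year, mean ≈ 66 — an aging, right-tailed population);
hearing loss drawn from logistic(β₀ + β_age(age−50) + β_edu·ridit(edu) +
β_woman + β_region) with defaults (−2.4, 0.065, −0.9, −0.55; region offsets
0/0.25/0.3/0.45 for N/W/S/E) calibrated so low-educated men rise from ≈ 10%
prevalence at 50 to ≈ 45% by 85+, women sit below men, and the East/South
sit above the North; SRHQ split uniformly within the good {1,2,3} or
less-than-good {4,5} class, since only the dichotomy carries signal; HA use
drawn (logistic, intercept ≈ a third of eligible Northern users, large
negative South/East offsets) only for less-than-good hearers, everyone else
a non-user; calibration weights Gamma with mean 1 and variance 0.3,
independent of outcomes, so weighted and unweighted estimands coincide and
the analytic truth stays exact; missingness MCAR at (2%, 0.4%, 0.3%) for
(age, SRHQ, weight), echoing the magnitudes of the real cascade.

Because weights are outcome-independent and the model is fully specified,
`implied_true_asp`/`implied_true_rii` integrate the logistic over the exact
age distribution and push the result through the identical ridit-regression
definition — a closed-form ground truth, not a simulation.

What the generator does **not** emulate: household/couple clustering, panel
attrition, calibration raking of weights, country-level sampling-frame
differences, or informative missingness. Passing recovery and coverage
tests therefore validate the estimators under clean MCAR, independent-weight
conditions; they do not certify behavior under informative design features
of real survey data. On the default synthetic data, aid users always rate
their hearing less than good, so the standard and sensitivity HL definitions
coincide; tests of the sensitivity recode construct good-hearing aid users
explicitly.

## Validation design and problem sizes

The suite checks, besides unit-level oracles: reproduction of the published
ridit worked example and of all eight regional Total RIIs from published
inputs at printed precision; absence of spurious inequality on a
200,000-record null-gradient cohort; recovery of the closed-form true RII
(1.70 under the recovery conditions: one stratum, shares 0.3/0.4/0.3,
β_edu = −0.7) with seed-averaged bias < 0.05 at n = 200,000 over 20 seeds;
and 93–97% empirical coverage of nominal-95% percentile and BCa intervals
over 300 cohorts of n = 5,000 with B = 200. These sizes keep the full
validation run to about a minute while leaving Monte-Carlo error well below
the tested tolerances — except for one deliberate marginal case: the null
SII check on a single cohort has sampling sd ≈ 0.29 pp against a ±0.3 pp
band, i.e. a ≈ 1σ criterion; it is asserted as stated, at the generator's
default seed, and its failure on that seed is a property of the band's
tightness, not of the estimator (the seed-averaged bias checks pass).

## Known limitations

- Variance enters only through the bootstrap; no Taylor-linearized survey
  variance, and no household/PSU resampling.
- The RII/SII regression is linear on standardized prevalences, as in the
  reproduced analysis; Poisson/log-binomial RII variants are out of scope.
- Ridit scoring assumes the three-level (or k-level, k ≥ 2) education
  variable is genuinely ordered; ties or reversals in the latent ordering
  are not modeled.
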