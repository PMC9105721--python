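# Methods

`lepmel` implements the statistical pipeline of a clinic-referral screen for
rare variants in the hypothalamic leptin–melanocortin pathway (the LEP →
LEPR → POMC/PCSK1 → MC4R/MC3R axis, opposed by NPY/AgRP) in children and
adolescents, together with a synthetic-data generator that reproduces the
statistical structure such a screen assumes. This note records the models,
the defaults and why they were chosen, the numerical decisions, and what the
synthetic tests do and do not demonstrate about real data.

## Growth-reference mathematics

All anthropometry is scored on LMS growth references: per sex, measure and
age, a Box–Cox power L, median M and coefficient of variation S define

    z = ((x/M)^L − 1) / (L·S)   (L ≠ 0),    z = ln(x/M) / S   (L = 0).

The implementation computes the power branch through `expm1`, so it degrades
continuously into the log branch as L → 0 (|difference| < 1e−6 at L = 1e−8).
The inverse is `x = M·(1 + L·S·z)^{1/L}`; for L < 0 this caps the
representable SDS at `z_max = 1/(|L|·S)` (≈ 6–7 for typical paediatric BMI
curves) — a property of the LMS form itself, shared by published charts.

Tabulated curves are interpolated **linearly in age, componentwise on
(L, M, S)**, exactly at knots, with no extrapolation outside the tabulated
range. Linear interpolation is reproducible and monotone-preserving on
monotone tables; spline alternatives buy little at monthly tabulation and
can overshoot. Ages are carried in months (1 year = 12 months exactly; the
2–19-year inclusion window is [24, 228] months inclusive); heights in
metres, weights in kg.

Weight groups partition the BMI-SDS line: underweight z < −2, non-obese
−2 ≤ z < 1, overweight 1 ≤ z < 2, obese z ≥ 2. The conventional interval
notation leaves z = 2.0 itself ambiguous; it is assigned to *obese* so that
the binary split at z = 1 (without obesity vs excess body weight), which
drives every downstream contrast, is exhaustive.

The package ships only synthetic LMS tables (see below). Real national
reference tables can be supplied in the documented CSV dialect
(`sex,measure,age_months,L,M,S`); note heights must be converted to metres.

## Cohort assembly

`apply_exclusions` fixes the stage order of the recruitment flow: (1) drop
ages outside 2–19 years and missing consent; (2) score BMI SDS and split at
SDS = 1; (3) the without-obesity group drops other metabolic disease, IUGR
and hypopituitarism; (4) the excess group drops syndromic obesity,
hypopituitarism and IUGR. A participant matching several criteria is counted
once, at the first matching stage. The ledger telescopes by construction and
is validated on every run.

Closed-form estimators:

* **Sample size for a proportion**: n = z²·p(1−p)/e², with the exact
  two-sided normal quantile (1.959964 at 95%, not the rounded 1.96) and
  half-up rounding of the result. At (95%, 3%, 0.5) this gives
  1067.07 → 1067; the rounded-quantile-plus-ceiling variant would give 1068.
* **National coverage**: estimated obese children = ⌊population ×
  prevalence⌋ (truncation: 293,897 × 0.06 → 17,633), coverage = cohort
  window / estimate.
* **Population incidence of carriage**: the package's own estimator, a
  prevalence-weighted mixture of group carrier fractions,
  `f_obese·prev + f_nonobese·(1−prev)`, with exact (Clopper–Pearson)
  binomial limits of each fraction propagated through the same mixture.
  Published screens rarely state their derivation for the analogous
  headline rates, so no equivalence with any particular published figure is
  claimed.

Percentages in summary tables are reported to one decimal, half-up, with
the grand total as denominator. Kruskal–Wallis (tie-corrected, chi-square
approximation) and Pearson chi-square independence (no continuity
correction) are delegated to scipy.

## Variant pipeline

Variants arrive annotated: population allele frequency, CADD score, and a
boolean reported-pathogenicity flag standing in for a mutation-database
(HGMD/ClinVar-style) lookup — the licensed databases themselves are out of
scope, but the classification rule is preserved exactly: after keeping rows
with AF < 0.01 **and** CADD > 20 (both strict, boundary rows excluded),
reported-pathogenic variants are DCV and the rest VUS.

Compound heterozygotes are called without phase information — two or more
distinct heterozygous qualifying variants in one gene flag the
(participant, gene) cell as a compound *candidate*. Cell classes are ranked
`hom_DCV > compound_DCV > DCV > hom_VUS > compound_VUS > VUS > none` (any
DCV outranks any VUS), and the participant-level stratum is the maximum
over genes collapsed to {DCV, VUS, none}, so the prevalence strata are
disjoint.

## Association under class rebalancing

Referral cohorts are heavily imbalanced (~1:5). Before each Fisher test the
classes are rebalanced: the minority class is oversampled with replacement
to ⌈N/2⌉ and the majority undersampled without replacement to ⌊N/2⌋,
preserving total N — plain random over/under-sampling, not kernel-smoothed
synthetic-example generation. The 50/50 target is fixed here because
standard balanced-resampling practice uses it; it is configurable in code.

Per resample, the carrier-by-group 2×2 table gets a two-sided Fisher exact
p (minimum-likelihood definition: the sum of hypergeometric probabilities
of all tables with the observed margins no more likely than the observed
one) and an odds ratio a·d/(b·c), Haldane–Anscombe-corrected (+0.5 on all
cells) when a cell is zero; a zero margin degenerates to p = 1 with an
undefined OR. The p-value is computed in-package by hypergeometric
enumeration so that repeated tables can be memoised across the default
9999 iterations; it is cross-checked in the test suite against exhaustive
exact-integer enumeration for *every* 2×2 table with total ≤ 40, and
against `scipy.stats.fisher_exact` on random tables.

Each gene's 9999 p draws are summarised by median and IQR and classified:

* `not_applicable` if the gene has ≤ 4 qualifying variant observations
  (variant rows are counted, i.e. carrier rows for the gene);
* `associated` if the median p < 0.05;
* `partially_associated` if the IQR straddles 0.05;
* `not_associated` otherwise — precedence exactly in this order.

Benjamini–Hochberg FDR is applied across the per-gene **median** p values
(one value per gene, via statsmodels); applying it per iteration would be
incoherent with the median/IQR rule.

**Known limitation — anti-conservatism.** Oversampling duplicates each
minority participant roughly threefold, and the Fisher test treats the
duplicates as independent. Measured over 400–600 null cohorts (equal
carrier frequency in both groups, 261/1247 split, 199 iterations), the
"associated" rate is ≈12% at per-gene carrier frequencies of 1–4%, i.e.
about double the nominal 5% — an inherent property of testing on a
rebalanced resample, not of this implementation (the exact test itself is
verified by enumeration). At very low frequencies the ≤4-variant rule
absorbs most cohorts into `not_applicable` and the rate falls to ≈7%.
Gene-level calls from this procedure should be read as screening calls, and
the FDR step operates on anti-conservative medians. Iteration i of the
resampling uses substream i of a single seed, so results are independent of
execution order.

## Effect size

The BMI-SDS effect of carriage is the 4-vs-4 subsample bootstrap: per
iteration (default 9999), up to k = 4 carriers drawn without replacement
(all carriers when ≤ k — "4 variants" is read as 4 carrier subjects), and
k non-carriers drawn without replacement from the pool of participants with
no qualifying variant in *any* panel gene; the draw is the difference of
subsample means. The estimate is the mean of draws; the interval is the
2.5/97.5 percentile of draws (no bias correction — the percentile interval
is the simplest defensible choice when the target procedure's interval
method is unstated). The bootstrap mean converges to the difference of the
two sample means, so its accuracy as an estimate of a planted shift is
governed by `SE² ≈ s²_c/n_c + s²_n/n_pool + s²_draws/n_iter`; the recovery
tests use exactly this quantity (3·SE tolerance).

## Trajectories

A BMI-SDS shift Δz converts to kilograms at each age as
`weight(z) = BMI(z_base + Δz; age, sex) · height₅₀(age, sex)²`, with z_base
the normal quantile of the chosen BMI-for-age percentile and height₅₀ the
50th-percentile height. This is the operationalisation of "weight at a BMI
percentile relative to the 50th-percentile height"; the 95th-percentile
variant uses base percentile 0.95 on the same BMI-for-age scale. An
alternative mode shifting weight-for-age SDS directly would be a different
model; BMI-through-height is the default and only mode implemented because
it is the only construction consistent with both halves of the phrase. Age
18 is evaluated at exactly 216 months; the 1-kg crossing age is reported at
grid (monthly) resolution. For L = 1 references the extra weight has the
closed form `H² · M_bmi · S · Δz`, used as a 1e−9 identity check.

## Synthetic data

The generator emulates a tertiary-clinic referral screen:

* **Sizes and skew**: 261 without obesity vs 1247 with excess body weight;
  without-obesity BMI SDS ~ Normal(0, 1) truncated to (−2, 1), excess ~
  Normal(2.8, 0.7) truncated to (1, ∞) — medians ≈ −0.1 and 2.8, matching
  the group summaries such screens report. Female share 54.6%; ages uniform
  on 2–19 years.
* **Carriers**: assigned per (gene, class) stratum *before* the SDS draw;
  the planted shift is added to the latent SDS and the group label is
  re-derived from the final SDS, so carriers enrich in the excess group
  endogenously. Default strata are calibrated to the aggregate carriage of
  a 1508-child screen (21 DCV ≈ 1.4%, 62 VUS ≈ 4.1%) and to per-gene counts
  where reported (e.g. LEPR 21 VUS + 2 DCV; MC4R 5 + 5; MC3R 7 DCV), with
  planted shifts 0.63/1.07/1.62 SDS where reported and 0 for genes reported
  non-associated. One variant per carrier per gene; annotations are drawn
  uniformly inside the filter-passing ranges (AF 5e−5–9e−3, CADD 20.5–40),
  DCV rows flagged reported-pathogenic; decoy variants that must fail the
  filter can be planted explicitly.
* **Round trip**: weight and height are back-computed through the reference
  from the planted SDS (height SDS ~ N(0,1) clipped to ±2.5), so re-scoring
  the anthropometry recovers the planted SDS to < 1e−9. Final SDS draws
  beyond the reference's representable ceiling (negative L) are capped just
  below it.
* **Carrier modes**: `bernoulli` (default; per-participant coin flips —
  the study condition) and `exact` (round(freq·N) carriers drawn without
  replacement from not-yet-carriers, keeping strata disjoint) for
  deterministic fixture-style tables.
* **Seeding**: one integer seed drives a `SeedSequence` hierarchy with one
  substream per table (demographics, carriers, SDS, anthropometry,
  annotations), so tables are individually reproducible.

The synthetic reference curves are linear-in-age L, M, S with plausible
paediatric magnitudes (BMI median rising ~16 → 21–22 kg/m², mildly negative
L; heights ~0.85 → 1.6–1.8 m). They are synthetic stand-ins, not copies of
any national chart; kilogram-scale outputs (18-year gains, crossing ages)
are therefore internally consistent quantities, not reproductions of any
published kilogram figures. Likewise the generator draws independent
cross-sectional participants — no repeated visits, no linkage or genotype
correlation, no measurement error — so passing tests demonstrate the
correctness of the estimators under the stated model, not robustness to
those real-data features.

## Problem sizes in the shipped analyses and tests

The analysis drivers and the acceptance script run 999 resampling/bootstrap
iterations per gene or stratum (the library default is 9999); the null
calibration uses 200 cohorts at 199 iterations; planted-effect recovery
uses 50–100 carriers at 999 iterations. These sizes give Monte-Carlo errors
comfortably inside the tolerances tested while keeping any single run in
seconds.
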