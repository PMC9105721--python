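# lepmel

Screening analysis for rare variants in the hypothalamic
leptin–melanocortin pathway (LEP → LEPR → POMC/PCSK1 → MC4R/MC3R, opposed
by NPY/AgRP) in paediatric cohorts. Built for biostatisticians and
clinical-genetics analysts who need to re-run, audit or power such a screen:
the package covers growth-chart scoring, cohort assembly, variant
filtering and classification, class-rebalanced association testing,
bootstrap effect sizes and weight-gain trajectory simulation — plus a
synthetic-cohort generator so every stage is testable without any
participant data.

## What it computes

* **BMI SDS** on LMS growth references, z = ((x/M)^L − 1)/(L·S), with the
  inverse x = M(1 + LSz)^{1/L}, linear age interpolation and weight-group
  cut-offs (without obesity: SDS < 1; excess body weight: SDS ≥ 1).
* **Cohort assembly**: a staged exclusion flow with a telescoping ledger,
  carrier-stratum summary tables, Kruskal–Wallis and chi-square tests, and
  the closed-form estimators n = z²p(1−p)/e² (required sample size),
  national screening coverage and population carriage incidence.
* **Variant pipeline**: keep rare (AF < 1%) and deleterious (CADD > 20)
  variants, classify reported-pathogenic rows as disease-causing variants
  (DCV) and the rest as variants of unknown significance (VUS), call
  phase-unaware compound heterozygotes, and build the participant × gene
  carrier matrix over the 11-gene panel (AGRP, LEP, LEPR, MC3R, MC4R, NPY,
  NPY1R, NPY5R, PCSK1, PCSK2, POMC).
* **Association per gene**: the cohort is rebalanced (minority class
  oversampled with replacement, majority undersampled without, to a 50/50
  split preserving N), a two-sided Fisher exact test with odds ratio is run
  on the carrier-by-group 2×2 table, and the procedure is iterated (default
  9999×). Genes are called *associated* (median p < 0.05), *partially
  associated* (IQR straddles 0.05), *not associated*, or *not applicable*
  (≤ 4 qualifying variants), with Benjamini–Hochberg FDR across gene-level
  median p values.
* **Effect size**: the 4-vs-4 subsample bootstrap — per iteration, up to 4
  carriers vs 4 variant-free participants, difference of subsample mean BMI
  SDS; mean of draws with a 2.5/97.5-percentile interval.
* **Trajectories**: a BMI-SDS shift Δz becomes kilograms by age via
  weight = BMI(z+Δz)·height₅₀², yielding the extra weight at 18 years and
  the age at which carriage first costs 1 kg.

See `docs/methods.md` for assumptions, defaults and known limitations
(notably the inherent anti-conservatism of testing on rebalanced
resamples).

## Worked example

```python
from lepmel import simulate, variants, association

reference = simulate.generate_lms_reference(seed=11)
config = simulate.SimulationConfig(seed=11)          # 261 vs 1247 children
cohort, table = simulate.generate_cohort(config, reference)

kept = variants.classify_variants(variants.filter_rare_deleterious(table))
matrix = variants.build_carrier_matrix(kept, cohort)

results = association.associate_genes(matrix, cohort, kept, n_iter=999, seed=11)
for r in results:
    if r.gene in ("LEPR", "MC4R", "PCSK1"):
        s = r.summary
        print(f"{r.gene:6s} median p={s.median_p:.4f} "
              f"IQR=({s.iqr_p[0]:.4f}, {s.iqr_p[1]:.4f}) "
              f"OR={s.or_median:5.2f}  {r.classification}")
```

prints

```
LEPR   median p=0.7531 IQR=(0.4521, 1.0000) OR= 1.13  not_associated
MC4R   median p=0.0154 IQR=(0.0077, 0.0309) OR=15.14  associated
PCSK1  median p=0.0909 IQR=(0.0343, 0.2648) OR= 3.52  partially_associated
```

MC4R carries the largest planted shifts in this simulated cohort (1.07 and
1.62 SDS for its VUS and DCV strata) and is called associated: across 999
rebalanced resamples the median Fisher p is 0.0154 and the whole IQR sits
below 0.05, with a median odds ratio of ≈15 for carriage among children
with excess body weight. PCSK1's weaker planted signal leaves its IQR
straddling 0.05 (partially associated), and LEPR's 0.63-SDS shift on ~20
carriers is too small for this cohort size, so it is not called — a useful
reminder that gene-level calls at these carrier counts are power-limited.

## Analysis scripts

`analysis/01_simulate_study.py` … `04_effect_sizes_and_trajectories.py`
run the study end to end on the synthetic cohort (simulation, recruitment
flow and summary tables, the association screen, effect sizes and
trajectories), printing what they find and writing tables under
`results/`. The `lepmel` command-line tool exposes the same stages as
subcommands (`simulate`, `sds`, `filter`, `associate`, `effect-size`,
`trajectory`, `report`).

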