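#!/usr/bin/env python
"""Build the synthetic study: growth reference, cohort and variant table.

Generates a 1508-child clinic cohort (261 without obesity, 1247 with excess
body weight) on a synthetic LMS reference, with rare leptin-melanocortin
panel variants planted at the study's carrier frequencies and effect sizes.
Full per-participant tables go to scratch/data/ (they are regenerated
deterministically from the seed); a small overview lands in results/.
"""

from pathlib import Path

from lepmel.simulate import SimulationConfig, generate_cohort, generate_lms_reference
from lepmel.variants import write_variant_table

SEED = 11
ROOT = Path(__file__).resolve().parent.parent


def main():
    scratch = ROOT / "scratch" / "data"
    results = ROOT / "results"
    scratch.mkdir(parents=True, exist_ok=True)
    results.mkdir(exist_ok=True)

    reference = generate_lms_reference(seed=SEED)
    config = SimulationConfig(seed=SEED)
    cohort, variants = generate_cohort(config, reference)

    reference.to_csv(scratch / "reference.csv")
    cohort.to_csv(scratch / "cohort.tsv", sep="\t", index=False)
    write_variant_table(variants, scratch / "variants.tsv")

    overview = (
        cohort.groupby("group")
        .agg(
            n=("id", "size"),
            pct_female=("sex", lambda s: round(100 * (s == "F").mean(), 1)),
            median_age=("age_years", "median"),
            median_bmi_sds=("bmi_sds", "median"),
        )
        .round(2)
    )
    overview.to_csv(results / "01_cohort_overview.tsv", sep="\t")
    print(f"simulated {len(cohort)} participants, {len(variants)} variant rows (seed {SEED})")
    print(overview)
    print(f"full tables -> {scratch}, overview -> {results / '01_cohort_overview.tsv'}")


if __name__ == "__main__":
    main()
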