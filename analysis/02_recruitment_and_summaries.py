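#!/usr/bin/env python
"""Recruitment flow, carrier-stratum summary and closed-form estimators.

Replays the staged exclusion flow over a synthetic referral table (1935
referred -> 1508 enrolled), tabulates the DCV/VUS carrier strata on an
exact-count cohort, and evaluates the sample-size, national-coverage and
population-incidence estimators.
"""

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from lepmel.cohort import (
    apply_exclusions,
    national_coverage,
    population_incidence,
    required_sample_size,
    round_half_up,
    summarize_groups,
)
from lepmel.simulate import (
    SimulationConfig,
    generate_cohort,
    generate_lms_reference,
    generate_referral_table,
)
from lepmel.variants import build_carrier_matrix, classify_variants, filter_rare_deleterious

SEED = 11
ROOT = Path(__file__).resolve().parent.parent


def main():
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    reference = generate_lms_reference(seed=SEED)

    raw = generate_referral_table(reference, seed=SEED)
    enrolled, ledger = apply_exclusions(raw, reference)
    ledger_dict = {k: v for k, v in asdict(ledger).items() if k != "reasons"}
    pd.Series(ledger_dict).to_csv(
        results / "02_recruitment_ledger.tsv", sep="\t", header=False
    )
    print(f"recruitment: {ledger.referred} referred -> "
          f"{ledger.enrolled_without} without obesity + "
          f"{ledger.enrolled_excess} with excess body weight enrolled")

    cohort, variants = generate_cohort(
        SimulationConfig(seed=SEED, carrier_mode="exact"), reference
    )
    matrix = build_carrier_matrix(
        classify_variants(filter_rare_deleterious(variants)), cohort
    )
    summary = summarize_groups(cohort, matrix)
    summary.to_csv(results / "02_carrier_summary.tsv", sep="\t", index=False)
    all_col = summary[summary["column"] == "all"].set_index("stratum")
    print(f"carriers: DCV {all_col.loc['DCV', 'n']} ({all_col.loc['DCV', 'pct']}%), "
          f"VUS {all_col.loc['VUS', 'n']} ({all_col.loc['VUS', 'pct']}%) of {len(cohort)}")

    n_dcv = int(all_col.loc["DCV", "n"])
    n_without = int((cohort["group"] == "without_obesity").sum())
    n_excess = int((cohort["group"] == "excess_body_weight").sum())
    rate, (lo, hi) = population_incidence(n_dcv, n_excess, 0, n_without, 0.06)
    estimated_obese, coverage = national_coverage(1079, 293897, 0.06)
    estimators = {
        "required_sample_size_95conf_3pct": required_sample_size(0.95, 0.03, 0.5),
        "estimated_obese_children": estimated_obese,
        "national_coverage_pct": round_half_up(100 * coverage, 1),
        "dcv_population_incidence": rate,
        "dcv_population_incidence_one_in": round(1 / rate) if rate else None,
        "dcv_incidence_ci_one_in": [round(1 / hi), round(1 / lo)] if lo else None,
    }
    with open(results / "02_estimators.json", "w") as fh:
        json.dump(estimators, fh, indent=2)
    print("estimators:", json.dumps(estimators))


if __name__ == "__main__":
    main()
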