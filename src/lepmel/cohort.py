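"""Cohort assembly and epidemiological summary statistics.

Covers the recruitment flow of a referral-based screen (staged exclusions
with a telescoping ledger), Table-style carrier-stratum summaries, the
routine nonparametric tests, and the closed-form estimators: required sample
size for a proportion, national screening coverage, and population incidence
of qualifying variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InputError, SchemaError
from .growth import GrowthReference, bmi_sds
from .variants import CarrierMatrix

__all__ = [
    "ExclusionLedger",
    "apply_exclusions",
    "summarize_groups",
    "kruskal_wallis",
    "chi_square_independence",
    "required_sample_size",
    "national_coverage",
    "population_incidence",
    "round_half_up",
]

RAW_COLUMNS = ["id", "sex", "age_years", "weight_kg", "height_m", "flags"]

#: Stage-3/4 exclusion reasons, in the order they are checked within a group.
WITHOUT_OBESITY_EXCLUSIONS = ("metabolic_other", "iugr", "hypopituitarism")
EXCESS_EXCLUSIONS = ("syndromic", "hypopituitarism", "iugr")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero toward +inf)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ExclusionLedger:
    """Stage counts of the recruitment flow plus per-participant reasons.

    Counts telescope: referred - excluded_age_consent = assessed, and per
    group assessed - excluded = enrolled.
    """

    referred: int = 0
    excluded_age_consent: int = 0
    assessed: int = 0
    assessed_without: int = 0
    assessed_excess: int = 0
    excluded_without: int = 0
    excluded_excess: int = 0
    enrolled_without: int = 0
    enrolled_excess: int = 0
    reasons: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        ok = (
            self.referred - self.excluded_age_consent == self.assessed
            and self.assessed_without + self.assessed_excess == self.assessed
            and self.assessed_without - self.excluded_without == self.enrolled_without
            and self.assessed_excess - self.excluded_excess == self.enrolled_excess
        )
        if not ok:
            raise InputError(f"exclusion ledger does not telescope: {self}")


def apply_exclusions(
    raw: pd.DataFrame,
    reference: GrowthReference,
    age_range_years: tuple[float, float] = (2.0, 19.0),
) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Run the staged inclusion/exclusion flow over a raw referral table.

    Stages, in fixed order (a participant is counted once, at the first
    matching stage):

    1. drop ages outside the inclusion window and missing consent;
    2. score BMI SDS and split into without-obesity (SDS < 1) vs excess
       body weight (SDS >= 1);
    3. without-obesity group drops metabolic_other / iugr / hypopituitarism;
    4. excess group drops syndromic / hypopituitarism / iugr.

    Returns the enrolled cohort (with ``bmi_sds`` and ``group`` columns) and
    the telescoping :class:`ExclusionLedger`.
    """
    missing = [c for c in RAW_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"raw cohort table missing columns: {missing}")
    ledger = ExclusionLedger(referred=len(raw))
    if len(raw) == 0:
        return raw.assign(bmi_sds=[], group=[]), ledger

    flags = raw["flags"].fillna("").astype(str).map(
        lambda s: frozenset(t for t in s.split(";") if t)
    )
    lo, hi = age_range_years
    age_bad = (raw["age_years"] < lo) | (raw["age_years"] > hi) | flags.map(
        lambda f: "age_out_of_range" in f
    )
    consent_bad = flags.map(lambda f: "no_consent" in f)
    stage1 = age_bad | consent_bad
    for pid, a in zip(raw.loc[stage1, "id"], age_bad[stage1]):
        ledger.reasons[str(pid)] = "age_out_of_range" if a else "no_consent"
    ledger.excluded_age_consent = int(stage1.sum())

    kept = raw.loc[~stage1].copy()
    ledger.assessed = len(kept)
    kept["bmi_sds"] = [
        bmi_sds(w, h, s, a * 12.0, reference)
        for w, h, s, a in zip(
            kept["weight_kg"], kept["height_m"], kept["sex"], kept["age_years"]
        )
    ]
    kept["group"] = np.where(
        kept["bmi_sds"] < 1.0, "without_obesity", "excess_body_weight"
    )
    without = kept["group"] == "without_obesity"
    ledger.assessed_without = int(without.sum())
    ledger.assessed_excess = int((~without).sum())

    kept_flags = flags.loc[kept.index]

    def first_reason(f, reasons):
        for r in reasons:
            if r in f:
                return r
        return None

    reasons3 = kept_flags.map(lambda f: first_reason(f, WITHOUT_OBESITY_EXCLUSIONS))
    reasons4 = kept_flags.map(lambda f: first_reason(f, EXCESS_EXCLUSIONS))
    drop_without = without & reasons3.notna()
    drop_excess = ~without & reasons4.notna()
    for pid, r in zip(kept.loc[drop_without, "id"], reasons3[drop_without]):
        ledger.reasons[str(pid)] = r
    for pid, r in zip(kept.loc[drop_excess, "id"], reasons4[drop_excess]):
        ledger.reasons[str(pid)] = r
    ledger.excluded_without = int(drop_without.sum())
    ledger.excluded_excess = int(drop_excess.sum())

    enrolled = kept.loc[~(drop_without | drop_excess)].reset_index(drop=True)
    ledger.enrolled_without = int((enrolled["group"] == "without_obesity").sum())
    ledger.enrolled_excess = int((enrolled["group"] == "excess_body_weight").sum())
    ledger.validate()
    return enrolled, ledger


def _median_iqr(x: pd.Series) -> tuple[float, float]:
    if len(x) == 0:
        return (float("nan"), float("nan"))
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return float(med), float(q3 - q1)


def summarize_groups(cohort: pd.DataFrame, carrier_matrix: CarrierMatrix) -> pd.DataFrame:
    """Carrier-stratum summary table (Total / DCV / VUS / No variant).

    For each stratum and each column (all, without obesity, excess body
    weight): n, percentage of the grand total (one decimal, half-up),
    female n and percentage of grand total, and median (IQR) of age and BMI
    SDS.  The DCV/VUS/No-variant strata are disjoint: a participant's
    stratum is their highest carrier class over all panel genes.
    """
    df = cohort.copy()
    df["stratum"] = carrier_matrix.participant_class.reindex(
        df["id"].astype(str)
    ).to_numpy()
    grand = len(df)
    rows = []
    masks = {
        "all": pd.Series(True, index=df.index),
        "without_obesity": df["group"] == "without_obesity",
        "excess_body_weight": df["group"] == "excess_body_weight",
    }
    strata = {
        "Total": pd.Series(True, index=df.index),
        "DCV": df["stratum"] == "DCV",
        "VUS": df["stratum"] == "VUS",
        "No variant": df["stratum"] == "none",
    }
    for sname, smask in strata.items():
        for cname, cmask in masks.items():
            sub = df.loc[smask & cmask]
            med_age, iqr_age = _median_iqr(sub["age_years"])
            med_sds, iqr_sds = _median_iqr(sub["bmi_sds"])
            n_f = int((sub["sex"] == "F").sum())
            rows.append(
                {
                    "stratum": sname,
                    "column": cname,
                    "n": len(sub),
                    "pct": round_half_up(100.0 * len(sub) / grand, 1) if grand else 0.0,
                    "n_female": n_f,
                    "pct_female": round_half_up(100.0 * n_f / grand, 1) if grand else 0.0,
                    "age_median": med_age,
                    "age_iqr": iqr_age,
                    "bmi_sds_median": med_sds,
                    "bmi_sds_iqr": iqr_sds,
                }
            )
    return pd.DataFrame(rows)


def kruskal_wallis(samples: list) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (k-1 df)."""
    if len(samples) < 2:
        raise InputError("Kruskal-Wallis needs at least 2 groups")
    if any(len(s) == 0 for s in samples):
        raise InputError("every group must be non-empty")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if np.ptp(np.concatenate(arrays)) == 0:
        # all observations identical: H = 0, p = 1 (scipy raises here)
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def chi_square_independence(table) -> tuple[float, float]:
    """Pearson chi-square test of independence (no continuity correction)."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise InputError("table must be at least 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise InputError("table must hold non-negative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise InputError("zero row/column margin")
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def required_sample_size(confidence: float, margin: float, proportion: float) -> int:
    """Minimum n to estimate a proportion: n = z^2 p(1-p) / e^2, half-up.

    Uses the exact two-sided normal quantile (1.959964 at 95%, not 1.96);
    e.g. (0.95, 0.03, 0.5) gives 1067.07 -> 1067.
    """
    for name, v in (("confidence", confidence), ("margin", margin),
                    ("proportion", proportion)):
        if not 0.0 < v < 1.0:
            raise DomainError(f"{name} must be in (0, 1), got {v}")
    z = stats.norm.ppf(1.0 - (1.0 - confidence) / 2.0)
    n = z**2 * proportion * (1.0 - proportion) / margin**2
    return int(round_half_up(n))


def national_coverage(
    n_cohort_in_window: int, population: int, prevalence: float
) -> tuple[int, float]:
    """Estimated obese children in a population window and cohort coverage.

    ``estimated_obese = floor(population * prevalence)`` (truncation, so
    293,897 x 0.06 -> 17,633); coverage is the cohort fraction of that
    estimate.
    """
    if population <= 0:
        raise DomainError("population must be positive")
    if not 0.0 < prevalence < 1.0:
        raise DomainError("prevalence must be in (0, 1)")
    estimated_obese = int(population * prevalence)
    if estimated_obese == 0:
        raise DomainError("estimated obese population is zero")
    return estimated_obese, n_cohort_in_window / estimated_obese


def population_incidence(
    carriers_obese: int,
    n_obese: int,
    carriers_nonobese: int,
    n_nonobese: int,
    prevalence: float,
    ci_level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Prevalence-weighted population rate of qualifying-variant carriage.

    Point estimate mixes the group carrier fractions by obesity prevalence:
    ``rate = f_ob * prev + f_non * (1 - prev)``.  The interval propagates
    Clopper-Pearson (exact binomial) limits of each fraction through the
    same mixture; this is this package's own estimator, documented here
    because published screens rarely state theirs.
    """
    if n_obese <= 0 or n_nonobese <= 0:
        raise InputError("group sizes must be positive")
    if carriers_obese > n_obese or carriers_nonobese > n_nonobese:
        raise InputError("carrier counts cannot exceed group sizes")
    if not 0.0 < prevalence < 1.0:
        raise DomainError("prevalence must be in (0, 1)")

    def cp_limits(k, n):
        alpha = 1.0 - ci_level
        lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
        hi = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
        return lo, hi

    f_ob = carriers_obese / n_obese
    f_non = carriers_nonobese / n_nonobese
    rate = f_ob * prevalence + f_non * (1.0 - prevalence)
    lo_ob, hi_ob = cp_limits(carriers_obese, n_obese)
    lo_non, hi_non = cp_limits(carriers_nonobese, n_nonobese)
    lo = lo_ob * prevalence + lo_non * (1.0 - prevalence)
    hi = hi_ob * prevalence + hi_non * (1.0 - prevalence)
    return rate, (lo, hi)
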