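"""LMS growth-reference mathematics.

Growth references parameterise the age- and sex-specific distribution of an
anthropometric measure by three curves: the Box-Cox power L, the median M and
the coefficient of variation S.  A measurement ``x`` converts to a standard
deviation score (SDS, z-score) by

    z = ((x / M)**L - 1) / (L * S)        for L != 0
    z = ln(x / M) / S                      for L == 0

and the inverse maps an SDS back to measurement units.  All SDS arithmetic in
the package (BMI SDS scoring, weight-gain trajectories, synthetic-cohort
construction) goes through this module.

Ages are carried in months internally; 1 year = 12 months exactly.  Heights
are in metres, weights in kg, BMI in kg/m^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import CoverageError, DomainError, ParameterError, SchemaError

__all__ = [
    "LMSRecord",
    "GrowthReference",
    "lms_zscore",
    "lms_value",
    "interpolate_lms",
    "bmi_sds",
    "classify_weight_group",
    "years_to_months",
    "months_to_years",
    "WEIGHT_GROUPS",
    "SEXES",
    "MEASURES",
]

SEXES = ("F", "M")
MEASURES = ("bmi", "height", "weight")
WEIGHT_GROUPS = ("underweight", "non_obese", "overweight", "obese")

#: L below this magnitude is treated as the log branch of the LMS transform.
_L_EPS = 1e-12

REFERENCE_COLUMNS = ["sex", "measure", "age_months", "L", "M", "S"]


def years_to_months(age_years: float) -> float:
    return float(age_years) * 12.0


def months_to_years(age_months: float) -> float:
    return float(age_months) / 12.0


@dataclass(frozen=True)
class LMSRecord:
    """One (sex, measure, age) point of a growth reference."""

    sex: str
    measure: str
    age_months: float
    L: float
    M: float
    S: float

    def __post_init__(self):
        if self.M <= 0 or self.S <= 0:
            raise ParameterError(
                f"LMS record requires M > 0 and S > 0; got M={self.M}, S={self.S} "
                f"for sex={self.sex}, measure={self.measure}, age={self.age_months}mo"
            )


def lms_zscore(x: float, rec: LMSRecord) -> float:
    """SDS of a measurement ``x`` under an LMS record.

    Uses ``expm1`` so the power branch degrades gracefully into the log
    branch as L -> 0.
    """
    if x <= 0:
        raise DomainError(f"measurement must be positive, got {x}")
    t = math.log(x / rec.M)
    if abs(rec.L) < _L_EPS:
        return t / rec.S
    return math.expm1(rec.L * t) / (rec.L * rec.S)


def lms_value(z: float, rec: LMSRecord) -> float:
    """Measurement value at SDS ``z`` (inverse of :func:`lms_zscore`)."""
    if abs(rec.L) < _L_EPS:
        return rec.M * math.exp(rec.S * z)
    w = rec.L * rec.S * z
    if 1.0 + w <= 0:
        raise DomainError(
            f"SDS {z} is outside the representable range for L={rec.L}, S={rec.S} "
            f"(1 + L*S*z = {1.0 + w} <= 0)"
        )
    # log1p keeps the power branch accurate down to L ~ 1e-12
    return rec.M * math.exp(math.log1p(w) / rec.L)


class GrowthReference:
    """Tabulated LMS curves keyed by (sex, measure), linearly interpolated in age.

    The canonical on-disk form is a CSV with header
    ``sex,measure,age_months,L,M,S``.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in REFERENCE_COLUMNS if c not in table.columns]
        if missing:
            raise SchemaError(f"growth reference missing columns: {missing}")
        df = table.loc[:, REFERENCE_COLUMNS].copy()
        df = df.sort_values(["sex", "measure", "age_months"], kind="mergesort")
        df = df.reset_index(drop=True)
        bad = df[(df["M"] <= 0) | (df["S"] <= 0)]
        if len(bad):
            r = bad.iloc[0]
            raise ParameterError(
                f"non-positive M or S at sex={r['sex']}, measure={r['measure']}, "
                f"age={r['age_months']}mo (M={r['M']}, S={r['S']})"
            )
        self._df = df
        self._curves: dict[tuple[str, str], tuple[np.ndarray, ...]] = {}
        for (sex, measure), sub in df.groupby(["sex", "measure"], sort=False):
            ages = sub["age_months"].to_numpy(dtype=float)
            if len(ages) and not np.all(np.diff(ages) > 0):
                raise ParameterError(
                    f"ages not strictly increasing for sex={sex}, measure={measure}"
                )
            self._curves[(sex, measure)] = (
                ages,
                sub["L"].to_numpy(dtype=float),
                sub["M"].to_numpy(dtype=float),
                sub["S"].to_numpy(dtype=float),
            )

    @property
    def table(self) -> pd.DataFrame:
        return self._df.copy()

    def keys(self) -> Iterable[tuple[str, str]]:
        return self._curves.keys()

    def coverage(self, sex: str, measure: str) -> tuple[float, float]:
        """(min, max) tabulated age in months for a (sex, measure) curve."""
        ages = self._key(sex, measure)[0]
        return float(ages[0]), float(ages[-1])

    def _key(self, sex: str, measure: str):
        try:
            return self._curves[(sex, measure)]
        except KeyError:
            raise SchemaError(
                f"reference has no curve for sex={sex!r}, measure={measure!r}"
            ) from None

    def interpolate(self, sex: str, measure: str, age_months: float) -> LMSRecord:
        ages, L, M, S = self._key(sex, measure)
        if age_months < ages[0] or age_months > ages[-1]:
            raise CoverageError(
                f"age {age_months}mo outside reference coverage "
                f"[{ages[0]}, {ages[-1]}]mo for sex={sex}, measure={measure} "
                "(no extrapolation)"
            )
        return LMSRecord(
            sex=sex,
            measure=measure,
            age_months=float(age_months),
            L=float(np.interp(age_months, ages, L)),
            M=float(np.interp(age_months, ages, M)),
            S=float(np.interp(age_months, ages, S)),
        )

    @classmethod
    def from_csv(cls, path) -> "GrowthReference":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self._df.to_csv(path, index=False)


def interpolate_lms(
    reference: GrowthReference, sex: str, measure: str, age_months: float
) -> LMSRecord:
    """Componentwise-linear interpolation of (L, M, S); exact at knots."""
    return reference.interpolate(sex, measure, age_months)


def bmi_sds(
    weight_kg: float,
    height_m: float,
    sex: str,
    age_months: float,
    reference: GrowthReference,
) -> float:
    """BMI-for-age SDS of a child given weight (kg) and height (m)."""
    if weight_kg <= 0 or height_m <= 0:
        raise DomainError(
            f"weight and height must be positive (got {weight_kg} kg, {height_m} m)"
        )
    rec = reference.interpolate(sex, "bmi", age_months)
    return lms_zscore(weight_kg / height_m**2, rec)


def classify_weight_group(z: float) -> str:
    """Weight group of a BMI SDS.

    underweight: z < -2; non_obese: -2 <= z < 1; overweight: 1 <= z < 2;
    obese: z >= 2.  The boundary z = 2 is assigned to obese so the binary
    split at z = 1 (without obesity vs excess body weight) stays exhaustive.
    """
    if not math.isfinite(z):
        raise DomainError(f"BMI SDS must be finite, got {z}")
    if z < -2.0:
        return "underweight"
    if z < 1.0:
        return "non_obese"
    if z < 2.0:
        return "overweight"
    return "obese"
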