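"""Weight-gain trajectories implied by a BMI-SDS effect size.

A carrier's excess BMI SDS is translated into kilograms on growth
percentile tables: at each age the baseline is the BMI at the chosen
percentile (z_base) evaluated at the 50th-percentile height, and the
carrier curve is the BMI at z_base + delta_z at the same height,

    weight(age, z) = BMI(z; age, sex) * height50(age, sex)^2 .

The difference curve locates the age at which carriage first costs an extra
kilogram and the weight difference at age 18 (216 months exactly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import CoverageError, DomainError, InputError
from .growth import GrowthReference, lms_value

__all__ = [
    "TrajectoryResult",
    "weight_at",
    "shifted_weight_curve",
    "one_kg_crossing_age",
    "cohort_average_gain",
]

AGE_18Y_MONTHS = 216.0


@dataclass(frozen=True)
class TrajectoryResult:
    sex: str
    base_percentile: float
    delta_z: float
    ages_months: np.ndarray
    base_weight_kg: np.ndarray
    shifted_weight_kg: np.ndarray
    delta_weight_kg: np.ndarray
    crossing_age_1kg: float | None
    delta_at_18y: float


def weight_at(
    age_months: float,
    sex: str,
    base_percentile: float,
    delta_z: float,
    reference: GrowthReference,
) -> float:
    """Body weight (kg) at a BMI percentile shifted by ``delta_z`` SDS,
    evaluated at the 50th-percentile height for that age and sex."""
    if not 0.0 < base_percentile < 1.0:
        raise DomainError(f"base_percentile must be in (0,1), got {base_percentile}")
    z_base = float(stats.norm.ppf(base_percentile))
    bmi_rec = reference.interpolate(sex, "bmi", age_months)
    height_rec = reference.interpolate(sex, "height", age_months)
    try:
        bmi = lms_value(z_base + delta_z, bmi_rec)
    except DomainError as e:
        raise CoverageError(
            f"SDS {z_base + delta_z:.3f} not representable at age {age_months}mo: {e}"
        ) from e
    height50 = lms_value(0.0, height_rec)
    return bmi * height50**2


def shifted_weight_curve(
    sex: str,
    base_percentile: float,
    delta_z: float,
    reference: GrowthReference,
    age_grid_months=None,
) -> TrajectoryResult:
    """Baseline vs shifted weight series over an age grid, with the 1-kg
    crossing age and the gain at 18 years (none of the grid is extrapolated)."""
    if age_grid_months is None:
        lo, hi = reference.coverage(sex, "bmi")
        age_grid_months = np.arange(max(lo, 24.0), min(hi, 228.0) + 0.5, 1.0)
    ages = np.asarray(age_grid_months, dtype=float)
    base = np.array(
        [weight_at(a, sex, base_percentile, 0.0, reference) for a in ages]
    )
    shifted = np.array(
        [weight_at(a, sex, base_percentile, delta_z, reference) for a in ages]
    )
    delta = shifted - base
    result = TrajectoryResult(
        sex=sex,
        base_percentile=base_percentile,
        delta_z=delta_z,
        ages_months=ages,
        base_weight_kg=base,
        shifted_weight_kg=shifted,
        delta_weight_kg=delta,
        crossing_age_1kg=_first_crossing(ages, delta),
        delta_at_18y=float(np.interp(AGE_18Y_MONTHS, ages, delta)),
    )
    return result


def _first_crossing(ages: np.ndarray, delta: np.ndarray, threshold: float = 1.0):
    hit = np.flatnonzero(delta >= threshold)
    return float(ages[hit[0]]) if len(hit) else None


def one_kg_crossing_age(result: TrajectoryResult) -> float | None:
    """Smallest grid age (months) with an extra weight of >= 1 kg, at grid
    resolution; None if the series never reaches 1 kg."""
    return _first_crossing(result.ages_months, result.delta_weight_kg)


def cohort_average_gain(
    estimates, sex: str, reference: GrowthReference, base_percentile: float = 0.5
) -> tuple[float, float]:
    """Mean and SD over effect estimates of the extra weight at 18 years.

    Each estimate's ``mean_delta`` is pushed through
    :func:`shifted_weight_curve` at the given base percentile; the SD is the
    population SD over estimates (0 for a single estimate).
    """
    estimates = list(estimates)
    if not estimates:
        raise InputError("need at least one effect estimate")
    gains = [
        shifted_weight_curve(sex, base_percentile, e.mean_delta, reference).delta_at_18y
        for e in estimates
    ]
    return float(np.mean(gains)), float(np.std(gains))
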