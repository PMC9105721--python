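"""Synthetic growth references, cohorts and annotated variant tables.

The generator emulates the structure of a referral-based paediatric
sequencing study: a clinic cohort heavily skewed towards excess body weight
(defaults: 261 without obesity vs 1247 with excess body weight), an 11-gene
leptin-melanocortin panel, rare qualifying variants carried by ~1.4% (DCV)
and ~4.1% (VUS) of participants, and planted per-gene BMI-SDS shifts in the
0.6-1.6 range for carriers.

Construction guarantees the round-trip property the downstream maths relies
on: each participant's weight and height are back-computed through the LMS
reference from a planted BMI SDS, so re-scoring the anthropometry recovers
the planted SDS to floating-point precision.

Carriers are assigned *before* the SDS draw and the planted effect is added
to the latent SDS; the obesity group label is then re-derived from the final
SDS, so carriers enrich in the excess-body-weight group endogenously rather
than by fiat.

A single integer seed drives a hierarchical stream (one substream per
generated table) so tables are individually reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CoverageError, InputError, ParameterError
from .growth import GrowthReference, LMSRecord, lms_value, years_to_months

__all__ = [
    "GeneSpec",
    "DecoySpec",
    "LMSCurveSpec",
    "SimulationConfig",
    "DEFAULT_GENE_SPECS",
    "default_curve_params",
    "generate_lms_reference",
    "generate_cohort",
    "generate_referral_table",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = [
    "id", "sex", "age_years", "weight_kg", "height_m", "bmi_sds", "group", "flags",
]


@dataclass(frozen=True)
class GeneSpec:
    """A planted carrier stratum: gene, frequency, effect and class."""

    gene: str
    carrier_frequency: float
    effect_size_sds: float
    variant_class: str = "VUS"  # DCV | VUS
    zygosity: str = "het"  # het | hom

    def __post_init__(self):
        if not 0.0 <= self.carrier_frequency <= 1.0:
            raise ParameterError(
                f"carrier_frequency must be in [0,1], got {self.carrier_frequency}"
            )
        if not math.isfinite(self.effect_size_sds):
            raise ParameterError("effect_size_sds must be finite")
        if self.variant_class not in ("DCV", "VUS"):
            raise ParameterError(f"variant_class must be DCV|VUS, got {self.variant_class}")
        if self.zygosity not in ("het", "hom"):
            raise ParameterError(f"zygosity must be het|hom, got {self.zygosity}")


@dataclass(frozen=True)
class DecoySpec:
    """A planted variant that must fail the rare/deleterious filter."""

    gene: str
    n: int
    population_af: float = 0.05
    cadd_phred: float = 25.0


# Default gene strata calibrated to the aggregate carrier strata of a
# 1508-child screen (21 DCV, 62 VUS) and to per-gene counts and BMI-SDS
# effects where the screen reports them; genes reported non-associated carry
# a null effect.  Frequencies are counts / 1508.
_N_REF = 1508
DEFAULT_GENE_SPECS: tuple[GeneSpec, ...] = (
    GeneSpec("LEPR", 21 / _N_REF, 0.63, "VUS"),
    GeneSpec("LEPR", 2 / _N_REF, 1.00, "DCV"),
    GeneSpec("PCSK1", 12 / _N_REF, 0.63, "VUS"),
    GeneSpec("PCSK1", 2 / _N_REF, 1.00, "DCV"),
    GeneSpec("POMC", 4 / _N_REF, 0.60, "VUS"),
    GeneSpec("POMC", 5 / _N_REF, 1.20, "DCV"),
    GeneSpec("MC4R", 5 / _N_REF, 1.07, "VUS"),
    GeneSpec("MC4R", 5 / _N_REF, 1.62, "DCV"),
    GeneSpec("MC3R", 7 / _N_REF, 0.85, "DCV"),
    GeneSpec("AGRP", 6 / _N_REF, 0.0, "VUS"),
    GeneSpec("PCSK2", 7 / _N_REF, 0.0, "VUS"),
    GeneSpec("NPY1R", 4 / _N_REF, 0.0, "VUS"),
    GeneSpec("NPY5R", 3 / _N_REF, 0.0, "VUS"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Group SDS distributions follow the referral-skewed shape of a tertiary
    obesity clinic: without-obesity ~ Normal(0, 1) truncated to (-2, 1);
    excess-body-weight ~ Normal(2.8, 0.7) truncated to (1, inf).
    """

    seed: int = 0
    n_without_obesity: int = 261
    n_excess: int = 1247
    sex_ratio_female: float = 0.546
    age_range_years: tuple[float, float] = (2.0, 19.0)
    baseline_sds_means: tuple[float, float] = (0.0, 2.8)  # (without, excess)
    baseline_sds_sd: tuple[float, float] = (1.0, 0.7)
    sds_bounds: tuple[tuple[float, float], tuple[float, float]] = (
        (-2.0, 1.0),
        (1.0, math.inf),
    )
    gene_specs: tuple[GeneSpec, ...] = DEFAULT_GENE_SPECS
    decoy_specs: tuple[DecoySpec, ...] = ()
    maf_range: tuple[float, float] = (5e-5, 9e-3)
    cadd_range: tuple[float, float] = (20.5, 40.0)
    carrier_mode: str = "bernoulli"  # bernoulli | exact

    def __post_init__(self):
        if self.n_without_obesity < 0 or self.n_excess < 0:
            raise ParameterError("cohort sizes must be >= 0")
        if not 0.0 <= self.sex_ratio_female <= 1.0:
            raise ParameterError("sex_ratio_female must be in [0,1]")
        lo, hi = self.age_range_years
        if not (2.0 <= lo < hi <= 19.0):
            raise ParameterError(
                f"age range must satisfy 2 <= min < max <= 19 years, got {self.age_range_years}"
            )
        if any(s <= 0 for s in self.baseline_sds_sd):
            raise ParameterError("baseline_sds_sd must be positive")
        if self.carrier_mode not in ("bernoulli", "exact"):
            raise ParameterError(f"carrier_mode must be bernoulli|exact, got {self.carrier_mode}")

    @property
    def n_total(self) -> int:
        return self.n_without_obesity + self.n_excess

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class LMSCurveSpec:
    """Linear-in-age curve parameters for one measure: v(age) = a + b * age_years."""

    L: tuple[float, float]
    M: tuple[float, float]
    S: tuple[float, float]

    def at(self, age_years: np.ndarray):
        def lin(ab):
            a, b = ab
            return a + b * age_years

        return lin(self.L), lin(self.M), lin(self.S)


def default_curve_params() -> dict[tuple[str, str], LMSCurveSpec]:
    """Smooth synthetic LMS curves with plausible paediatric magnitudes.

    BMI medians rise from ~16 kg/m^2 at age 2 to ~21-22 at 19 with a mildly
    negative Box-Cox L (right-skewed BMI); heights rise roughly linearly from
    ~0.88 m to ~1.63-1.77 m.  These are synthetic stand-ins for (not copies
    of) national growth charts, in the same units and ranges.
    """
    params = {}
    for sex, (bmi_a, bmi_b, h_a, h_b, w_a, w_b) in {
        "F": (15.6, 0.33, 0.845, 0.046, 10.0, 2.55),
        "M": (15.8, 0.35, 0.850, 0.049, 10.4, 2.75),
    }.items():
        params[(sex, "bmi")] = LMSCurveSpec(L=(-1.2, 0.0), M=(bmi_a, bmi_b), S=(0.105, 0.0015))
        params[(sex, "height")] = LMSCurveSpec(L=(1.0, 0.0), M=(h_a, h_b), S=(0.042, 0.0))
        params[(sex, "weight")] = LMSCurveSpec(L=(-0.3, 0.0), M=(w_a, w_b), S=(0.14, 0.0))
    return params


def generate_lms_reference(
    sex_set=("F", "M"),
    age_grid_months=None,
    curve_params: dict[tuple[str, str], LMSCurveSpec] | None = None,
    seed: int = 0,
) -> GrowthReference:
    """Tabulate synthetic LMS curves on a monthly age grid.

    Deterministic given parameters (the seed is accepted for interface
    symmetry with the stochastic generators).  The grid must strictly
    increase and cover at least 24-228 months (ages 2-19 years).
    """
    if age_grid_months is None:
        age_grid_months = np.arange(24, 229, 1, dtype=float)
    ages = np.asarray(age_grid_months, dtype=float)
    if ages.ndim != 1 or len(ages) < 2 or not np.all(np.diff(ages) > 0):
        raise ParameterError("age grid must be 1-D and strictly increasing")
    if ages[0] > 24 or ages[-1] < 228:
        raise CoverageError("age grid must cover at least 24-228 months")
    if curve_params is None:
        curve_params = default_curve_params()
    age_years = ages / 12.0
    frames = []
    for sex in sex_set:
        for measure in ("bmi", "height", "weight"):
            spec = curve_params[(sex, measure)]
            L, M, S = spec.at(age_years)
            if np.any(M <= 0) or np.any(S <= 0):
                bad = ages[(M <= 0) | (S <= 0)][0]
                raise ParameterError(
                    f"curve params give non-positive M or S at sex={sex}, "
                    f"measure={measure}, age={bad}mo"
                )
            frames.append(
                pd.DataFrame(
                    {"sex": sex, "measure": measure, "age_months": ages,
                     "L": L, "M": M, "S": S}
                )
            )
    return GrowthReference(pd.concat(frames, ignore_index=True))


def _truncnorm_draws(rng, n, mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _carrier_indicator(rng, n, freq, mode, available=None):
    if mode == "bernoulli":
        return rng.random(n) < freq
    # exact mode: round(freq * n) carriers drawn without replacement from the
    # participants not yet carrying anything, so strata stay disjoint and
    # participant-level counts are hit exactly
    k = int(round(freq * n))
    flag = np.zeros(n, dtype=bool)
    pool = np.flatnonzero(available) if available is not None else np.arange(n)
    if k > 0:
        flag[rng.choice(pool, size=min(k, len(pool)), replace=False)] = True
    return flag


def generate_cohort(
    config: SimulationConfig, reference: GrowthReference
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort and its annotated variant table.

    Returns ``(cohort, variants)``: the cohort with back-computed
    anthropometry and the planted BMI SDS, and one variant row per carrier
    per gene stratum (plus any configured decoys, which are built to fail
    the rare/deleterious filter).
    """
    n = config.n_total
    ss = np.random.SeedSequence(config.seed)
    rng_demo, rng_carrier, rng_sds, rng_anthro, rng_annot = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    # demographics
    sex = np.where(rng_demo.random(n) < config.sex_ratio_female, "F", "M")
    lo_y, hi_y = config.age_range_years
    age_years = rng_demo.uniform(lo_y, hi_y, size=n)

    # latent group labels at the configured sizes, then per-group SDS draws
    latent_excess = np.zeros(n, dtype=bool)
    latent_excess[: config.n_excess] = True
    rng_demo.shuffle(latent_excess)
    sds = np.empty(n)
    for is_excess in (False, True):
        mask = latent_excess == is_excess
        g = 1 if is_excess else 0
        lo, hi = config.sds_bounds[g]
        sds[mask] = _truncnorm_draws(
            rng_sds, int(mask.sum()), config.baseline_sds_means[g],
            config.baseline_sds_sd[g], lo, hi,
        )

    # carriers per stratum, planted effect added to the latent SDS
    carrier_flags: list[np.ndarray] = []
    available = np.ones(n, dtype=bool)
    for spec in config.gene_specs:
        expected = spec.carrier_frequency * n
        if 0 < expected < 1:
            warnings.warn(
                f"{spec.gene} ({spec.variant_class}): expected carriers "
                f"{expected:.2f} < 1; the gene may have zero carriers"
            )
        flag = _carrier_indicator(
            rng_carrier, n, spec.carrier_frequency, config.carrier_mode, available
        )
        available &= ~flag
        sds = sds + flag * spec.effect_size_sds
        carrier_flags.append(flag)

    # group re-derived from the final SDS
    group = np.where(sds < 1.0, "without_obesity", "excess_body_weight")

    # anthropometry back-computed through the reference
    height_sds = np.clip(rng_anthro.normal(0.0, 1.0, size=n), -2.5, 2.5)
    age_months = years_to_months(1) * age_years
    height = np.empty(n)
    weight = np.empty(n)
    for i in range(n):
        h_rec = reference.interpolate(sex[i], "height", age_months[i])
        b_rec = reference.interpolate(sex[i], "bmi", age_months[i])
        if b_rec.L < 0:
            # a negative Box-Cox L caps the expressible SDS at 1/(|L|*S);
            # cap extreme draws just below it, as tabulated charts do
            z_max = 0.97 / (-b_rec.L * b_rec.S)
            if sds[i] > z_max:
                sds[i] = z_max
        height[i] = lms_value(height_sds[i], h_rec)
        weight[i] = lms_value(sds[i], b_rec) * height[i] ** 2

    ids = np.array([f"P{i:05d}" for i in range(n)])
    cohort = pd.DataFrame(
        {"id": ids, "sex": sex, "age_years": age_years, "weight_kg": weight,
         "height_m": height, "bmi_sds": sds, "group": group, "flags": ""}
    )

    # variant rows: one per carrier per stratum, annotations consistent with
    # the class and passing the rare/deleterious filter
    rows = []
    for j, spec in enumerate(config.gene_specs):
        idx = np.flatnonzero(carrier_flags[j])
        af = rng_annot.uniform(*config.maf_range, size=len(idx))
        cadd = rng_annot.uniform(*config.cadd_range, size=len(idx))
        for k, i in enumerate(idx):
            rows.append(
                (ids[i], spec.gene, f"{spec.gene}:sim{j}:{k}", spec.zygosity,
                 af[k], cadd[k], spec.variant_class == "DCV")
            )
    for j, decoy in enumerate(config.decoy_specs):
        idx = rng_annot.choice(n, size=min(decoy.n, n), replace=False)
        for k, i in enumerate(idx):
            rows.append(
                (ids[i], decoy.gene, f"{decoy.gene}:decoy{j}:{k}", "het",
                 decoy.population_af, decoy.cadd_phred, False)
            )
    variants = pd.DataFrame(
        rows,
        columns=["participant_id", "gene", "variant_id", "zygosity",
                 "population_af", "cadd_phred", "reported_pathogenic"],
    )
    return cohort, variants


def generate_referral_table(
    reference: GrowthReference,
    n_referred: int = 1935,
    n_age_consent: int = 109,
    n_without: int = 472,
    n_excess: int = 1354,
    n_excluded_without: int = 211,
    n_excluded_excess: int = 107,
    seed: int = 0,
) -> pd.DataFrame:
    """Raw referral table whose exclusion flow telescopes to given stage counts.

    Defaults reproduce a tertiary-clinic recruitment flow: 1935 referred,
    109 dropped for age/consent, 472 vs 1354 assessed without/with excess
    body weight, 211 and 107 group-specific exclusions, enrolling 261 + 1247.
    Exclusion reasons are planted as flags; BMI SDS values place each row in
    its intended group.
    """
    if n_age_consent + n_without + n_excess != n_referred:
        raise InputError("stage counts must telescope: referred = age/consent + groups")
    if n_excluded_without > n_without or n_excluded_excess > n_excess:
        raise InputError("group exclusions cannot exceed group sizes")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    rows = []

    def add(i, sds, flags, age=None):
        age = float(rng.uniform(3.0, 18.0)) if age is None else age
        sex = "F" if rng.random() < 0.5 else "M"
        # anthropometry needs a covered age even for rows planted outside the
        # inclusion window (they are dropped before SDS scoring anyway)
        lo, hi = reference.coverage(sex, "bmi")
        age_mo = min(max(age * 12.0, lo), hi)
        h_rec = reference.interpolate(sex, "height", age_mo)
        b_rec = reference.interpolate(sex, "bmi", age_mo)
        h = lms_value(0.0, h_rec)
        w = lms_value(sds, b_rec) * h**2
        rows.append((f"R{i:05d}", sex, age, w, h, flags))

    i = 0
    for _ in range(n_age_consent):
        # split stage-1 exclusions between age violations and missing consent
        if rng.random() < 0.5:
            add(i, 0.0, "", age=float(rng.choice([1.2, 1.5, 20.0, 21.0])))
        else:
            add(i, 0.0, "no_consent")
        i += 1
    without_reasons = ["metabolic_other", "iugr", "hypopituitarism"]
    for k in range(n_without):
        flags = without_reasons[k % 3] if k < n_excluded_without else ""
        add(i, float(rng.uniform(-1.8, 0.9)), flags)
        i += 1
    excess_reasons = ["syndromic", "hypopituitarism", "iugr"]
    for k in range(n_excess):
        flags = excess_reasons[k % 3] if k < n_excluded_excess else ""
        add(i, float(rng.uniform(1.1, 4.0)), flags)
        i += 1
    return pd.DataFrame(
        rows, columns=["id", "sex", "age_years", "weight_kg", "height_m", "flags"]
    )
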