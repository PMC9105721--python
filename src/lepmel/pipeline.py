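"""End-to-end orchestration: filter -> classify -> carrier matrix ->
association (+FDR) -> effect sizes -> trajectories, from a single config.

The JSON report is the normative machine interface; per-stage TSVs sit next
to it.  Reruns with the same config are byte-identical in every numeric
output (one seed drives documented substreams per stage).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import associate_genes
from .cohort import summarize_groups
from .effect_size import stratified_effect_sizes
from .errors import ConfigError, SchemaError
from .growth import GrowthReference, bmi_sds
from .trajectory import cohort_average_gain, shifted_weight_curve
from .variants import (
    PANEL_GENES,
    build_carrier_matrix,
    classify_variants,
    filter_rare_deleterious,
    read_variant_table,
)

__all__ = ["RunConfig", "run_pipeline", "validate_report", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = 1

_REQUIRED_REPORT_KEYS = (
    "schema_version", "package_version", "seed", "stages", "associations",
    "effect_sizes", "trajectories", "carrier_summary",
)


@dataclass(frozen=True)
class RunConfig:
    cohort_path: str
    variants_path: str
    reference_path: str
    output_dir: str
    maf_max: float = 0.01
    cadd_min: float = 20.0
    n_iter: int = 9999
    k_subsample: int = 4
    seed: int = 0
    genes: tuple[str, ...] = PANEL_GENES
    trajectory_percentiles: tuple[float, ...] = (0.5, 0.95)
    trajectory_sexes: tuple[str, ...] = ("F", "M")

    def __post_init__(self):
        if not 0.0 < self.maf_max <= 1.0:
            raise ConfigError(f"maf_max must be in (0,1], got {self.maf_max}")
        if self.cadd_min < 0:
            raise ConfigError("cadd_min must be >= 0")
        if self.n_iter < 1 or self.k_subsample < 1:
            raise ConfigError("n_iter and k_subsample must be >= 1")
        unknown = [g for g in self.genes if g not in PANEL_GENES]
        if unknown:
            raise ConfigError(f"genes not in panel: {unknown}")
        if any(not 0.0 < p < 1.0 for p in self.trajectory_percentiles):
            raise ConfigError("trajectory percentiles must be in (0,1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("genes", "trajectory_percentiles", "trajectory_sexes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        try:
            return cls(**raw)
        except TypeError as e:
            raise ConfigError(str(e)) from e


def validate_report(report: dict) -> None:
    missing = [k for k in _REQUIRED_REPORT_KEYS if k not in report]
    if missing:
        raise SchemaError(f"report missing keys: {missing}")
    if report["schema_version"] != REPORT_SCHEMA_VERSION:
        raise SchemaError(f"unsupported report schema {report['schema_version']}")


def _load_cohort(path, reference: GrowthReference) -> pd.DataFrame:
    cohort = pd.read_csv(path, sep="\t", dtype={"id": str})
    required = ["id", "sex", "age_years", "weight_kg", "height_m"]
    missing = [c for c in required if c not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort table missing columns: {missing}")
    if "bmi_sds" not in cohort.columns:
        cohort["bmi_sds"] = [
            bmi_sds(w, h, s, a * 12.0, reference)
            for w, h, s, a in zip(
                cohort["weight_kg"], cohort["height_m"], cohort["sex"],
                cohort["age_years"],
            )
        ]
    if "group" not in cohort.columns:
        cohort["group"] = np.where(
            cohort["bmi_sds"] < 1.0, "without_obesity", "excess_body_weight"
        )
    return cohort


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full screen and write the report plus per-stage TSVs."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    def log(stage, n_in, n_out, **extra):
        stages.append({"stage": stage, "rows_in": n_in, "rows_out": n_out, **extra})

    reference = GrowthReference.from_csv(config.reference_path)
    cohort = _load_cohort(config.cohort_path, reference)
    log("load_cohort", int(len(cohort)), int(len(cohort)))

    variants = read_variant_table(config.variants_path)
    filtered = filter_rare_deleterious(
        variants, maf_max=config.maf_max, cadd_min=config.cadd_min
    )
    log("filter_rare_deleterious", int(len(variants)), int(len(filtered)),
        **filtered.attrs.get("filter_log", {}))
    classified = classify_variants(filtered)
    log("classify_variants", int(len(filtered)), int(len(classified)))

    matrix = build_carrier_matrix(classified, cohort)
    log("carrier_matrix", int(len(classified)),
        int(matrix.matrix.shape[0] * matrix.matrix.shape[1]))

    seeds = np.random.SeedSequence(config.seed).spawn(2)
    assoc = associate_genes(
        matrix, cohort, classified, genes=config.genes,
        n_iter=config.n_iter, seed=seeds[0],
    )
    log("association", int(len(config.genes)), int(len(assoc)))
    estimates = stratified_effect_sizes(
        matrix, cohort, n_iter=config.n_iter, k=config.k_subsample, seed=seeds[1]
    )
    log("effect_sizes", int(len(config.genes) * 2), int(len(estimates)))

    trajectories = []
    for sex in config.trajectory_sexes:
        for pct in config.trajectory_percentiles:
            for est in estimates:
                curve = shifted_weight_curve(sex, pct, est.mean_delta, reference)
                trajectories.append(
                    {
                        "sex": sex, "base_percentile": pct, "gene": est.gene,
                        "variant_class": est.variant_class,
                        "delta_z": est.mean_delta,
                        "crossing_age_1kg_months": curve.crossing_age_1kg,
                        "delta_at_18y_kg": curve.delta_at_18y,
                    }
                )
        if estimates:
            mean_gain, sd_gain = cohort_average_gain(estimates, sex, reference)
            trajectories.append(
                {
                    "sex": sex, "base_percentile": 0.5, "gene": "ALL",
                    "variant_class": "DCV+VUS", "delta_z": None,
                    "crossing_age_1kg_months": None,
                    "delta_at_18y_kg": mean_gain, "sd_at_18y_kg": sd_gain,
                }
            )
    log("trajectories", int(len(estimates)), int(len(trajectories)))

    summary = summarize_groups(cohort, matrix)

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": stages,
        "associations": [
            {
                "gene": r.gene,
                "n_variants": r.n_variants,
                "median_p": r.summary.median_p,
                "q1_p": r.summary.iqr_p[0],
                "q3_p": r.summary.iqr_p[1],
                "or_median": r.summary.or_median,
                "or_ci_low": r.summary.or_ci[0],
                "or_ci_high": r.summary.or_ci[1],
                "classification": r.classification,
                "fdr_adjusted_median_p": r.fdr_adjusted_median_p,
            }
            for r in assoc
        ],
        "effect_sizes": [
            {
                "gene": e.gene, "variant_class": e.variant_class,
                "n_carriers": e.n_carriers, "n_iter": e.n_iter,
                "mean_delta": e.mean_delta,
                "ci_low": e.ci_95[0], "ci_high": e.ci_95[1],
            }
            for e in estimates
        ],
        "trajectories": trajectories,
        "carrier_summary": summary.to_dict(orient="records"),
    }
    validate_report(report)

    pd.DataFrame(report["associations"]).to_csv(
        outdir / "associations.tsv", sep="\t", index=False
    )
    pd.DataFrame(report["effect_sizes"]).to_csv(
        outdir / "effect_sizes.tsv", sep="\t", index=False
    )
    pd.DataFrame(trajectories).to_csv(
        outdir / "trajectories.tsv", sep="\t", index=False
    )
    summary.to_csv(outdir / "carrier_summary.tsv", sep="\t", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    return report


def _jsonable(obj):
    """Recursively map non-finite floats to None for strict JSON output."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return float(obj) if np.isfinite(obj) else None
    if isinstance(obj, np.integer):
        return int(obj)
    return obj
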