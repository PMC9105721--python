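"""Annotated-variant ingestion, filtering, classification and carrier matrix.

The screen targets an 11-gene panel covering the hypothalamic
leptin-melanocortin axis (LEP -> LEPR -> POMC/PCSK1 -> MC4R/MC3R, opposed by
NPY/AgRP).  Variants arrive as an already-annotated TSV (one row per
participant x variant) carrying a population allele frequency, a CADD
deleteriousness score and a reported-pathogenicity flag standing in for a
mutation-database (HGMD/ClinVar-style) disease-causing annotation.

The qualifying filter keeps rare (population AF < 1%) and predicted
deleterious (CADD > 20) variants, both inequalities strict.  Qualifying
variants previously reported disease-causing are DCV; the remainder are VUS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, ParseError, ReferentialError, SchemaError

__all__ = [
    "PANEL_GENES",
    "PANEL_INHERITANCE",
    "CARRIER_CLASSES",
    "CLASS_RANK",
    "VARIANT_COLUMNS",
    "CarrierMatrix",
    "read_variant_table",
    "write_variant_table",
    "filter_rare_deleterious",
    "classify_variants",
    "detect_compound_heterozygotes",
    "build_carrier_matrix",
    "participant_base_class",
]

#: The gene panel, with inheritance pattern(s): autosomal dominant (AD),
#: autosomal recessive (AR), mitochondrial (Mu) or not established (NA).
PANEL_INHERITANCE: dict[str, tuple[str, ...]] = {
    "AGRP": ("AD", "AR", "Mu"),
    "LEP": ("AR",),
    "LEPR": ("AR",),
    "MC3R": ("AD",),
    "MC4R": ("AD",),
    "NPY": ("NA",),
    "NPY1R": ("NA",),
    "NPY5R": ("NA",),
    "PCSK1": ("AR",),
    "PCSK2": ("NA",),
    "POMC": ("AR",),
}
PANEL_GENES: tuple[str, ...] = tuple(PANEL_INHERITANCE)

VARIANT_COLUMNS = [
    "participant_id",
    "gene",
    "variant_id",
    "zygosity",
    "population_af",
    "cadd_phred",
    "reported_pathogenic",
]

#: Carrier-matrix cell classes in precedence order (low to high).  Compound
#: calls are "compound-candidate": made from >= 2 distinct heterozygous
#: qualifying variants in one gene without phase information.
CARRIER_CLASSES = (
    "none",
    "VUS",
    "compound_VUS",
    "hom_VUS",
    "DCV",
    "compound_DCV",
    "hom_DCV",
)
CLASS_RANK = {c: i for i, c in enumerate(CARRIER_CLASSES)}

_BOOL_TOKENS = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False,
}


def _parse_bool(tok, line: int):
    s = str(tok).strip().lower()
    if s not in _BOOL_TOKENS:
        raise ParseError(f"reported_pathogenic must be boolean, got {tok!r}", line)
    return _BOOL_TOKENS[s]


def read_variant_table(path, strict_genes: bool = True) -> pd.DataFrame:
    """Read the normative variant TSV into a typed DataFrame.

    Row-level problems raise :class:`ParseError` with the 1-based file line
    (header is line 1).  Unknown genes raise in strict mode, warn otherwise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"variant table missing columns: {missing}")
    df = df.loc[:, VARIANT_COLUMNS]
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        gene = row.gene
        if gene not in PANEL_GENES:
            if strict_genes:
                raise ParseError(f"gene {gene!r} not in panel", line)
            warnings.warn(f"line {line}: gene {gene!r} not in panel, kept as-is")
        zyg = str(row.zygosity).strip()
        if zyg not in ("het", "hom"):
            raise ParseError(f"zygosity must be het|hom, got {row.zygosity!r}", line)
        try:
            af = float(row.population_af)
            cadd = float(row.cadd_phred)
        except (TypeError, ValueError):
            raise ParseError(
                f"non-numeric annotation (af={row.population_af!r}, "
                f"cadd={row.cadd_phred!r})", line
            ) from None
        if not 0.0 <= af <= 1.0:
            raise ParseError(f"population_af must be in [0,1], got {af}", line)
        if cadd < 0:
            raise ParseError(f"cadd_phred must be >= 0, got {cadd}", line)
        records.append(
            (str(row.participant_id), gene, str(row.variant_id), zyg, af, cadd,
             _parse_bool(row.reported_pathogenic, line))
        )
    return pd.DataFrame.from_records(records, columns=VARIANT_COLUMNS)


def write_variant_table(variants: pd.DataFrame, path) -> None:
    variants.loc[:, VARIANT_COLUMNS].to_csv(path, sep="\t", index=False)


def filter_rare_deleterious(
    variants: pd.DataFrame, maf_max: float = 0.01, cadd_min: float = 20.0
) -> pd.DataFrame:
    """Keep rare (AF < maf_max) and deleterious (CADD > cadd_min) variants.

    Both thresholds strict; boundary rows are excluded.  Rows with a missing
    annotation are rejected (never silently kept); removal counts per
    criterion are recorded in ``result.attrs["filter_log"]``.
    """
    missing = [c for c in ("population_af", "cadd_phred") if c not in variants.columns]
    if missing:
        raise SchemaError(f"variant table missing annotations: {missing}")
    af = pd.to_numeric(variants["population_af"], errors="coerce")
    cadd = pd.to_numeric(variants["cadd_phred"], errors="coerce")
    unannotated = af.isna() | cadd.isna()
    common = af >= maf_max
    benign = cadd <= cadd_min
    keep = ~unannotated & ~common & ~benign
    out = variants.loc[keep].copy()
    out.attrs["filter_log"] = {
        "input": int(len(variants)),
        "removed_missing_annotation": int(unannotated.sum()),
        "removed_common": int((common & ~unannotated).sum()),
        "removed_low_cadd": int((benign & ~unannotated & ~common).sum()),
        "kept": int(keep.sum()),
    }
    return out


def classify_variants(variants: pd.DataFrame) -> pd.DataFrame:
    """Attach ``variant_class``: DCV iff reported pathogenic, else VUS."""
    out = variants.copy()
    flag = out["reported_pathogenic"].astype(bool)
    out["variant_class"] = np.where(flag, "DCV", "VUS")
    return out


def _cell_class(sub: pd.DataFrame) -> str:
    """Carrier class of one (participant, gene) cell from its classified rows."""
    is_dcv = (sub["variant_class"] == "DCV").to_numpy()
    is_hom = (sub["zygosity"] == "hom").to_numpy()
    n_het = int((~is_hom).sum())
    if is_dcv.any():
        if (is_hom & is_dcv).any():
            return "hom_DCV"
        if n_het >= 2:
            # any second het variant (DCV or VUS) makes a compound candidate
            return "compound_DCV"
        return "DCV"
    if is_hom.any():
        return "hom_VUS"
    if n_het >= 2:
        return "compound_VUS"
    return "VUS"


def detect_compound_heterozygotes(variants: pd.DataFrame) -> pd.DataFrame:
    """Per-(participant, gene) carrier class with compound/hom calls.

    Duplicate (participant_id, variant_id) rows are deduplicated with a
    warning before counting distinct heterozygous variants.
    """
    if "variant_class" not in variants.columns:
        raise SchemaError("variants must be classified first (variant_class column)")
    dup = variants.duplicated(subset=["participant_id", "variant_id"])
    if dup.any():
        warnings.warn(f"dropping {int(dup.sum())} duplicate (participant, variant) rows")
        variants = variants.loc[~dup]
    rows = [
        {"participant_id": pid, "gene": gene, "carrier_class": _cell_class(sub)}
        for (pid, gene), sub in variants.groupby(["participant_id", "gene"], sort=True)
    ]
    return pd.DataFrame(rows, columns=["participant_id", "gene", "carrier_class"])


def participant_base_class(cell_class: str) -> str:
    """Collapse a carrier-matrix class to its DCV/VUS/none stratum."""
    if cell_class == "none":
        return "none"
    return "DCV" if CLASS_RANK[cell_class] >= CLASS_RANK["DCV"] else "VUS"


@dataclass
class CarrierMatrix:
    """Participant x gene carrier classes plus the participant-level stratum.

    ``matrix`` has one row per cohort participant and one column per panel
    gene, entries from :data:`CARRIER_CLASSES`.  ``participant_class`` is the
    precedence maximum over genes collapsed to {none, VUS, DCV} — the
    disjoint strata used in carrier-prevalence summaries.
    """

    matrix: pd.DataFrame
    participant_class: pd.Series = field(repr=False)

    def carriers(self, gene: str, min_class: str = "VUS") -> pd.Series:
        """Boolean carrier indicator for one gene at or above ``min_class``."""
        ranks = self.matrix[gene].map(CLASS_RANK)
        return ranks >= CLASS_RANK[min_class]


def build_carrier_matrix(
    variants: pd.DataFrame,
    cohort: pd.DataFrame,
    panel: tuple[str, ...] = PANEL_GENES,
) -> CarrierMatrix:
    """Pivot classified variants into the participant x gene carrier matrix."""
    if "id" not in cohort.columns:
        raise SchemaError("cohort table must have an 'id' column")
    ids = cohort["id"].astype(str)
    if ids.duplicated().any():
        raise InputError("cohort ids must be unique")
    known = set(ids)
    if len(variants):
        unknown = sorted(set(variants["participant_id"].astype(str)) - known)
        if unknown:
            raise ReferentialError(
                f"variant rows reference {len(unknown)} unknown participants: "
                f"{unknown[:10]}"
            )
    matrix = pd.DataFrame("none", index=pd.Index(ids, name="participant_id"),
                          columns=list(panel))
    if len(variants):
        cells = detect_compound_heterozygotes(variants)
        for row in cells.itertuples(index=False):
            if row.gene in matrix.columns:
                matrix.at[row.participant_id, row.gene] = row.carrier_class
    ranks = matrix.apply(lambda col: col.map(CLASS_RANK))
    top = ranks.max(axis=1)
    argmax = ranks.idxmax(axis=1)
    best = pd.Series(
        [matrix.at[i, g] for i, g in zip(matrix.index, argmax)], index=matrix.index
    ).where(top > 0, "none")
    participant_class = best.map(participant_base_class)
    participant_class.name = "participant_class"
    return CarrierMatrix(matrix=matrix, participant_class=participant_class)
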