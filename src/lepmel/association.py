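"""Per-gene carrier-vs-group association under class-rebalanced resampling.

A referral cohort is heavily imbalanced (roughly 1:5 without vs with excess
body weight), so a single Fisher test over-weights the majority class.  The
screen instead rebalances the classes before each test: the minority class
is oversampled with replacement and the majority class undersampled without
replacement to a 50/50 split preserving the total cohort size, the 2x2
carrier-by-group table is tabulated on the resample, and a two-sided Fisher
exact p and odds ratio are computed.  Iterating this (default 9999 times)
yields a p-value distribution per gene; the gene is called

* ``associated``            if the median p is below 0.05,
* ``partially_associated``  if the IQR straddles 0.05,
* ``not_associated``        otherwise,
* ``not_applicable``        when the gene has 4 or fewer qualifying
  variant observations (too few for the distribution to be meaningful).

Gene-level median p values are corrected across the panel with the
Benjamini-Hochberg FDR step-up.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, InputError
from .variants import CarrierMatrix, PANEL_GENES

__all__ = [
    "ContingencyTable2x2",
    "PDistributionSummary",
    "AssociationResult",
    "fisher_exact",
    "rebalance_sample",
    "resampled_association",
    "classify_gene_association",
    "bh_fdr",
    "associate_genes",
]

#: Relative slack when comparing hypergeometric point probabilities in the
#: two-sided (minimum-likelihood) p-value, guarding against float ties.
_P_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Carrier-by-group counts: a/b carriers/non-carriers in the excess
    group, c/d in the without-obesity group."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InputError("2x2 counts must be non-negative")


@dataclass(frozen=True)
class PDistributionSummary:
    """Median/IQR of resampled Fisher p draws and the OR distribution."""

    n_iter: int
    median_p: float
    iqr_p: tuple[float, float]
    or_median: float
    or_ci: tuple[float, float]


@dataclass(frozen=True)
class AssociationResult:
    gene: str
    summary: PDistributionSummary
    n_variants: int
    classification: str
    fdr_adjusted_median_p: float | None = None


@lru_cache(maxsize=200_000)
def _fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by hypergeometric enumeration (minimum-likelihood
    rule: sum the probabilities of all tables with the observed margins that
    are no more likely than the observed one)."""
    n_row1 = a + b
    col1 = a + c
    n = a + b + c + d
    lo = max(0, n_row1 + col1 - n)
    hi = min(n_row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, n_row1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _P_REL_TOL)].sum())
    return min(p, 1.0)


def fisher_exact(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher exact p and odds ratio for a 2x2 table.

    OR = (a*d)/(b*c), with the Haldane-Anscombe +0.5 on every cell when any
    cell is zero.  A zero margin makes the test degenerate: p = 1 and the OR
    is undefined (NaN).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0, float("nan")
    if min(a, b, c, d) == 0:
        oratio = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        oratio = (a * d) / (b * c)
    return _fisher_p(a, b, c, d), oratio


def rebalance_sample(group_is_excess, seed) -> np.ndarray:
    """Balanced resample indices: minority class oversampled with
    replacement (ceil(N/2) draws), majority undersampled without replacement
    (floor(N/2) draws); output size equals the input size.

    ``group_is_excess`` is a boolean vector over the cohort; the returned
    indices point into it, so any per-participant attribute (carrier status
    in particular) travels with each index.
    """
    g = np.asarray(group_is_excess, dtype=bool)
    n = len(g)
    idx_excess = np.flatnonzero(g)
    idx_without = np.flatnonzero(~g)
    if len(idx_excess) == 0 or len(idx_without) == 0:
        raise InputError("both classes must be non-empty")
    if len(idx_without) <= len(idx_excess):
        minority, majority = idx_without, idx_excess
    else:
        minority, majority = idx_excess, idx_without
    n_minority = math.ceil(n / 2)
    n_majority = n // 2
    if len(majority) < n_majority:
        raise InputError(
            f"majority class ({len(majority)}) smaller than undersample "
            f"target ({n_majority})"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    drawn_minority = rng.choice(minority, size=n_minority, replace=True)
    drawn_majority = rng.choice(majority, size=n_majority, replace=False)
    return np.concatenate([drawn_minority, drawn_majority])


def resampled_association(
    carrier_matrix: CarrierMatrix | np.ndarray,
    gene: str | None,
    group_is_excess,
    n_iter: int = 9999,
    seed: int = 0,
) -> PDistributionSummary:
    """Fisher p/OR distribution for one gene over rebalanced resamples.

    ``carrier_matrix`` may be a :class:`CarrierMatrix` (with ``gene`` naming
    the column) or a pre-computed boolean carrier vector (``gene`` ignored).
    Iteration i uses substream i of the seed, so the draw sequence does not
    depend on execution order.
    """
    if n_iter < 1:
        raise InputError("n_iter must be >= 1")
    if isinstance(carrier_matrix, CarrierMatrix):
        if gene not in PANEL_GENES:
            raise InputError(f"gene {gene!r} not in panel")
        carrier = carrier_matrix.carriers(gene).to_numpy()
    else:
        carrier = np.asarray(carrier_matrix, dtype=bool)
    g = np.asarray(group_is_excess, dtype=bool)
    if len(carrier) != len(g):
        raise InputError("carrier and group vectors must align")
    if carrier.sum() == 0:
        warnings.warn("no carriers in the cohort; degenerate summary (all p = 1)")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(n_iter)
    p_draws = np.empty(n_iter)
    or_draws = np.empty(n_iter)
    for i in range(n_iter):
        idx = rebalance_sample(g, np.random.default_rng(streams[i]))
        g_i = g[idx]
        c_i = carrier[idx]
        a = int(np.count_nonzero(c_i & g_i))
        b = int(np.count_nonzero(~c_i & g_i))
        c = int(np.count_nonzero(c_i & ~g_i))
        d = int(np.count_nonzero(~c_i & ~g_i))
        p_draws[i], or_draws[i] = fisher_exact(ContingencyTable2x2(a, b, c, d))
    q1, med, q3 = np.percentile(p_draws, [25, 50, 75])
    finite_or = or_draws[np.isfinite(or_draws)]
    if len(finite_or):
        or_med = float(np.median(finite_or))
        or_ci = tuple(float(v) for v in np.percentile(finite_or, [2.5, 97.5]))
    else:
        or_med, or_ci = float("nan"), (float("nan"), float("nan"))
    return PDistributionSummary(
        n_iter=n_iter,
        median_p=float(med),
        iqr_p=(float(q1), float(q3)),
        or_median=or_med,
        or_ci=or_ci,
    )


def classify_gene_association(summary: PDistributionSummary, n_variants: int) -> str:
    """Apply the median/IQR classification rule (precedence in this order):

    n_variants <= 4 -> not_applicable; median p < 0.05 -> associated;
    Q1 <= 0.05 <= Q3 -> partially_associated; otherwise not_associated.
    """
    if n_variants <= 4:
        return "not_applicable"
    if summary.median_p < 0.05:
        return "associated"
    q1, q3 = summary.iqr_p
    if q1 <= 0.05 <= q3:
        return "partially_associated"
    return "not_associated"


def bh_fdr(p_values) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DomainError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def associate_genes(
    carrier_matrix: CarrierMatrix,
    cohort: pd.DataFrame,
    variants: pd.DataFrame,
    genes=PANEL_GENES,
    n_iter: int = 9999,
    seed: int = 0,
) -> list[AssociationResult]:
    """Full panel association: per-gene resampled Fisher summaries, the
    median/IQR classification, and BH-FDR over the gene-level median p."""
    g = (cohort["group"] == "excess_body_weight").to_numpy()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(len(genes))
    results = []
    for gene, stream in zip(genes, streams):
        n_var = int((variants["gene"] == gene).sum()) if len(variants) else 0
        summary = resampled_association(
            carrier_matrix, gene, g, n_iter=n_iter, seed=stream
        )
        results.append(
            AssociationResult(
                gene=gene,
                summary=summary,
                n_variants=n_var,
                classification=classify_gene_association(summary, n_var),
            )
        )
    adjusted = bh_fdr([r.summary.median_p for r in results])
    return [
        AssociationResult(
            gene=r.gene, summary=r.summary, n_variants=r.n_variants,
            classification=r.classification, fdr_adjusted_median_p=adj,
        )
        for r, adj in zip(results, adjusted)
    ]
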