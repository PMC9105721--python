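"""Bootstrap effect of carrying a qualifying variant on BMI SDS.

The estimator repeatedly (default 9999 times) compares a small carrier
subsample against a small non-carrier subsample: per iteration, up to k = 4
carriers are drawn without replacement (all carriers if there are <= k) and
exactly k non-carriers are drawn without replacement from the pool of
participants with no qualifying variant in *any* panel gene; the draw is the
difference of subsample means (carriers minus non-carriers).  The estimate
is the mean of the draws and the interval the 2.5/97.5 percentile of draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .variants import CarrierMatrix, CLASS_RANK, participant_base_class

__all__ = [
    "EffectSizeEstimate",
    "subsample_effect_size",
    "stratified_effect_sizes",
    "recovery_se",
]


@dataclass(frozen=True)
class EffectSizeEstimate:
    gene: str
    variant_class: str
    n_carriers: int
    n_iter: int
    mean_delta: float
    ci_95: tuple[float, float]
    delta_draws: np.ndarray


def recovery_se(carrier_sds, noncarrier_sds, estimate: EffectSizeEstimate) -> float:
    """Standard error of ``mean_delta`` as an estimate of the underlying
    carrier/non-carrier location shift.

    The bootstrap mean converges (in n_iter) to the difference of the two
    *sample* means, so the dominant error is the finite-sample variance of
    those means; the residual Monte-Carlo term shrinks with n_iter.
    """
    carriers = np.asarray(carrier_sds, dtype=float)
    pool = np.asarray(noncarrier_sds, dtype=float)
    s_c = float(np.var(carriers, ddof=1)) if len(carriers) > 1 else 0.0
    s_n = float(np.var(pool, ddof=1)) if len(pool) > 1 else 0.0
    s_d = float(np.var(estimate.delta_draws, ddof=1)) if estimate.n_iter > 1 else 0.0
    return float(
        np.sqrt(s_c / len(carriers) + s_n / len(pool) + s_d / estimate.n_iter)
    )


def subsample_effect_size(
    carrier_sds,
    noncarrier_sds,
    n_iter: int = 9999,
    k: int = 4,
    seed: int | np.random.SeedSequence = 0,
    gene: str = "",
    variant_class: str = "",
) -> EffectSizeEstimate:
    """k-vs-k subsample bootstrap of the carrier/non-carrier BMI SDS gap."""
    carriers = np.asarray(carrier_sds, dtype=float)
    pool = np.asarray(noncarrier_sds, dtype=float)
    if len(carriers) < 1:
        raise InputError("need at least one carrier")
    if len(pool) < k:
        raise InputError(f"need at least k={k} non-carriers, got {len(pool)}")
    if n_iter < 1:
        raise InputError("n_iter must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    draws = np.empty(n_iter)
    take_all = len(carriers) <= k
    for i in range(n_iter):
        carr = carriers if take_all else rng.choice(carriers, size=k, replace=False)
        non = rng.choice(pool, size=k, replace=False)
        draws[i] = carr.mean() - non.mean()
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return EffectSizeEstimate(
        gene=gene,
        variant_class=variant_class,
        n_carriers=len(carriers),
        n_iter=n_iter,
        mean_delta=float(draws.mean()),
        ci_95=(float(lo), float(hi)),
        delta_draws=draws,
    )


def stratified_effect_sizes(
    carrier_matrix: CarrierMatrix,
    cohort: pd.DataFrame,
    n_iter: int = 9999,
    k: int = 4,
    seed: int = 0,
) -> list[EffectSizeEstimate]:
    """One effect estimate per (gene, DCV/VUS) stratum present in the matrix.

    The non-carrier pool is the set of participants with no qualifying
    variant in any panel gene.  Empty strata are skipped.
    """
    sds = cohort.set_index(cohort["id"].astype(str))["bmi_sds"]
    m = carrier_matrix.matrix
    pool_ids = carrier_matrix.participant_class.index[
        carrier_matrix.participant_class == "none"
    ]
    pool = sds.loc[pool_ids].to_numpy()
    estimates = []
    strata = [
        (gene, cls)
        for gene in m.columns
        for cls in ("DCV", "VUS")
    ]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(len(strata))
    for (gene, cls), stream in zip(strata, streams):
        cell_base = m[gene].map(
            lambda c: participant_base_class(c) if CLASS_RANK[c] > 0 else "none"
        )
        ids = m.index[cell_base == cls]
        if len(ids) == 0:
            continue
        estimates.append(
            subsample_effect_size(
                sds.loc[ids].to_numpy(), pool, n_iter=n_iter, k=k,
                seed=stream, gene=gene, variant_class=cls,
            )
        )
    return estimates
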