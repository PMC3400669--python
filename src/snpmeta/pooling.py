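"""Heterogeneity assessment and fixed/random-effects pooling.

Fixed-effects pooling uses the Mantel-Haenszel estimator with the
Robins-Breslow-Greenland variance for its log; random-effects pooling is
DerSimonian-Laird.  :func:`select_and_pool` applies the Q-test rule:
fixed effects iff the heterogeneity p-value exceeds ``alpha_het``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientStudiesError, UndefinedEffectError, ValidationError
from .genetic_models import (
    CorrectionPolicy,
    EffectEstimate,
    FourfoldTable,
    GeneticModel,
    Z_95,
    build_contingency,
    log_odds_ratio,
)
from .study_io import StudyCollection

__all__ = [
    "PoolingMethod",
    "HeterogeneityResult",
    "PooledResult",
    "cochran_q",
    "pool_mantel_haenszel",
    "pool_dersimonian_laird",
    "select_and_pool",
    "stratified_analysis",
    "pooled_results_dataframe",
]


class PoolingMethod(Enum):
    MANTEL_HAENSZEL_FIXED = "mantel_haenszel_fixed"
    DERSIMONIAN_LAIRD_RANDOM = "dersimonian_laird_random"


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with I^2 and the DerSimonian-Laird tau^2."""

    q: float
    df: int
    p_value: float
    i_squared: float
    tau_squared: float


@dataclass(frozen=True)
class PooledResult:
    """A pooled odds ratio with its 95% CI and provenance."""

    or_pooled: float
    ci_low: float
    ci_high: float
    method: PoolingMethod
    weights: tuple[float, ...]
    heterogeneity: HeterogeneityResult | None
    k: int
    stratum_label: str | None = None
    study_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 < self.ci_low <= self.or_pooled <= self.ci_high):
            raise ValidationError(
                f"CI ({self.ci_low}, {self.ci_high}) must bracket OR {self.or_pooled}"
            )
        w = np.asarray(self.weights)
        if len(w) and (w.min() < 0 or abs(w.sum() - 1.0) > 1e-9):
            raise ValidationError("weights must be non-negative and sum to 1")

    @property
    def log_or(self) -> float:
        return math.log(self.or_pooled)


def _as_arrays(effects: Sequence[EffectEstimate]) -> tuple[np.ndarray, np.ndarray]:
    theta = np.array([e.log_or for e in effects], dtype=float)
    se = np.array([e.se for e in effects], dtype=float)
    return theta, se


def cochran_q(effects: Sequence[EffectEstimate]) -> HeterogeneityResult:
    """Cochran's Q on fixed inverse-variance weights, with DL tau^2.

    tau^2 = max(0, (Q - df) / (sum(w) - sum(w^2)/sum(w))) — the
    DerSimonian-Laird moment estimator.
    """
    k = len(effects)
    if k < 2:
        raise InsufficientStudiesError(
            f"heterogeneity assessment needs >= 2 studies, got {k}"
        )
    theta, se = _as_arrays(effects)
    w = 1.0 / se**2
    mean = float((w * theta).sum() / w.sum())
    q = float((w * (theta - mean) ** 2).sum())
    df = k - 1
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return HeterogeneityResult(
        q=q,
        df=df,
        p_value=float(stats.chi2.sf(q, df=df)),
        i_squared=i2,
        tau_squared=tau2,
    )


def pool_mantel_haenszel(
    tables: Sequence[FourfoldTable],
    correction: CorrectionPolicy = "haldane",
    stratum_label: str | None = None,
) -> PooledResult:
    """Mantel-Haenszel fixed-effects pooled OR with the RBG interval.

    OR_MH = sum(a_i d_i / n_i) / sum(b_i c_i / n_i); the CI comes from
    the Robins-Breslow-Greenland variance of ln OR_MH.  Raw cells enter
    the MH sums uncorrected (MH tolerates zero cells natively); the
    attached heterogeneity is computed on the per-study Woolf effects
    under the given correction policy.
    """
    k = len(tables)
    if k < 1:
        raise InsufficientStudiesError("Mantel-Haenszel pooling needs >= 1 table")
    cells = np.array([t.cells() for t in tables], dtype=float)
    a, b, c, d = cells.T
    n = cells.sum(axis=1)
    r_i = a * d / n
    s_i = b * c / n
    r, s = r_i.sum(), s_i.sum()
    if r == 0 or s == 0:
        raise UndefinedEffectError(
            "Mantel-Haenszel estimate undefined: a diagonal product sum is zero"
        )
    or_mh = r / s

    # Robins-Breslow-Greenland variance of ln(OR_MH)
    p_i = (a + d) / n
    q_i = (b + c) / n
    var = (
        (p_i * r_i).sum() / (2 * r * r)
        + (p_i * s_i + q_i * r_i).sum() / (2 * r * s)
        + (q_i * s_i).sum() / (2 * s * s)
    )
    se = math.sqrt(var)
    log_or = math.log(or_mh)

    het = None
    if k >= 2:
        het = cochran_q([log_odds_ratio(t, correction) for t in tables])
    weights = tuple(s_i / s) if s > 0 else tuple(np.full(k, 1.0 / k))
    return PooledResult(
        or_pooled=or_mh,
        ci_low=math.exp(log_or - Z_95 * se),
        ci_high=math.exp(log_or + Z_95 * se),
        method=PoolingMethod.MANTEL_HAENSZEL_FIXED,
        weights=weights,
        heterogeneity=het,
        k=k,
        stratum_label=stratum_label,
        study_labels=tuple(t.study_label for t in tables),
    )


def pool_dersimonian_laird(
    effects: Sequence[EffectEstimate],
    stratum_label: str | None = None,
) -> PooledResult:
    """DerSimonian-Laird random-effects pooled OR.

    Weights w*_i = 1/(se_i^2 + tau^2) with tau^2 from :func:`cochran_q`;
    when Q <= df the estimator reduces to the fixed inverse-variance
    pool.
    """
    k = len(effects)
    if k < 2:
        raise InsufficientStudiesError(
            f"DerSimonian-Laird pooling needs >= 2 studies, got {k}"
        )
    het = cochran_q(effects)
    theta, se = _as_arrays(effects)
    w = 1.0 / (se**2 + het.tau_squared)
    mean = float((w * theta).sum() / w.sum())
    pooled_se = 1.0 / math.sqrt(w.sum())
    return PooledResult(
        or_pooled=math.exp(mean),
        ci_low=math.exp(mean - Z_95 * pooled_se),
        ci_high=math.exp(mean + Z_95 * pooled_se),
        method=PoolingMethod.DERSIMONIAN_LAIRD_RANDOM,
        weights=tuple(w / w.sum()),
        heterogeneity=het,
        k=k,
        stratum_label=stratum_label,
        study_labels=tuple(e.study_label for e in effects),
    )


def select_and_pool(
    studies: StudyCollection,
    model: GeneticModel,
    alpha_het: float = 0.05,
    correction: CorrectionPolicy = "haldane",
    stratum_label: str | None = None,
) -> PooledResult:
    """Pool one contrast under the Q-test model-selection rule.

    Fixed effects (Mantel-Haenszel) iff the Q-test p-value is strictly
    greater than ``alpha_het``; otherwise random effects
    (DerSimonian-Laird).
    """
    if not 0 < alpha_het < 1:
        raise ValidationError(f"alpha_het must lie in (0, 1), got {alpha_het}")
    k = len(studies)
    if k < 2:
        raise InsufficientStudiesError(
            f"model-selected pooling needs >= 2 studies, got {k}"
        )
    tables = [build_contingency(s, model) for s in studies]
    effects = [log_odds_ratio(t, correction) for t in tables]
    het = cochran_q(effects)
    if het.p_value > alpha_het:
        return pool_mantel_haenszel(tables, correction, stratum_label=stratum_label)
    return pool_dersimonian_laird(effects, stratum_label=stratum_label)


def stratified_analysis(
    studies: StudyCollection,
    stratifier: str,
    model: GeneticModel,
    alpha_het: float = 0.05,
    correction: CorrectionPolicy = "haldane",
) -> list[PooledResult]:
    """Apply :func:`select_and_pool` independently within each stratum.

    Model selection is per-stratum.  A stratum with fewer than two
    studies is an error naming the stratum.
    """
    results = []
    for name, subset in studies.partition(stratifier):
        if len(subset) < 2:
            raise InsufficientStudiesError(
                f"stratum {name!r} has {len(subset)} study(ies); need >= 2"
            )
        results.append(
            select_and_pool(
                subset, model, alpha_het, correction, stratum_label=name
            )
        )
    return results


def pooled_results_dataframe(
    results: Iterable[tuple[GeneticModel, str, PooledResult]]
) -> pd.DataFrame:
    """Flatten (model, stratum, result) triples into a report table."""
    rows = []
    for model, stratum, res in results:
        het = res.heterogeneity
        rows.append(
            {
                "stratum": stratum,
                "model": model.value,
                "k": res.k,
                "or": res.or_pooled,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "method": res.method.value,
                "q": het.q if het else np.nan,
                "q_p_value": het.p_value if het else np.nan,
                "i_squared": het.i_squared if het else np.nan,
                "tau_squared": het.tau_squared if het else np.nan,
            }
        )
    return pd.DataFrame(rows)
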