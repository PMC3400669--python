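"""Publication-bias diagnostics and leave-one-out sensitivity analysis.

Egger's regression (original unweighted form: standardized effect on
precision), the Begg-Mazumdar rank correlation, funnel-plot data export,
and one-way leave-one-out re-pooling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateRegressionError, InsufficientStudiesError, ValidationError
from .genetic_models import CorrectionPolicy, EffectEstimate, GeneticModel, Z_95
from .pooling import PooledResult, select_and_pool
from .study_io import StudyCollection

__all__ = [
    "EggerResult",
    "BeggResult",
    "FunnelPoint",
    "FunnelData",
    "LeaveOneOutRow",
    "egger_test",
    "begg_rank_test",
    "funnel_data",
    "leave_one_out",
]


@dataclass(frozen=True)
class EggerResult:
    """Egger regression intercept test for funnel asymmetry."""

    intercept: float
    intercept_se: float
    t_statistic: float
    p_value: float
    k: int
    slope: float


@dataclass(frozen=True)
class BeggResult:
    """Begg-Mazumdar rank correlation (Kendall tau-b numerator form)."""

    statistic: float  # normalised Kendall tau in [-1, 1]
    score: int  # concordant minus discordant pairs
    z: float
    p_value: float
    k: int


@dataclass(frozen=True)
class FunnelPoint:
    study_label: str
    log_or: float
    se: float

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValidationError("funnel point se must be positive")


@dataclass(frozen=True)
class FunnelData:
    """Funnel scatter plus pseudo-95%-CI guide lines for plotting."""

    points: tuple[FunnelPoint, ...]
    center: float | None
    guides: pd.DataFrame  # columns: se, ci_low, ci_high

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"study": p.study_label, "log_or": p.log_or, "se": p.se}
                for p in self.points
            ]
        )


@dataclass(frozen=True)
class LeaveOneOutRow:
    omitted_label: str
    result: PooledResult


def egger_test(effects: Sequence[EffectEstimate]) -> EggerResult:
    """Egger's linear regression test for funnel-plot asymmetry.

    Ordinary least squares of the standardized effect (log OR / SE) on
    precision (1 / SE); the intercept's t-statistic on k - 2 degrees of
    freedom is the test.  A nonzero intercept indicates small-study
    (funnel) asymmetry.
    """
    k = len(effects)
    if k < 3:
        raise InsufficientStudiesError(f"Egger's test needs >= 3 studies, got {k}")
    theta = np.array([e.log_or for e in effects])
    se = np.array([e.se for e in effects])
    precision = 1.0 / se
    if np.ptp(precision) == 0:
        raise DegenerateRegressionError(
            "all studies share the same standard error; Egger regression is degenerate"
        )
    fit = stats.linregress(precision, theta / se)
    t = fit.intercept / fit.intercept_stderr
    p = 2.0 * float(stats.t.sf(abs(t), df=k - 2))
    return EggerResult(
        intercept=float(fit.intercept),
        intercept_se=float(fit.intercept_stderr),
        t_statistic=float(t),
        p_value=p,
        k=k,
        slope=float(fit.slope),
    )


def begg_rank_test(effects: Sequence[EffectEstimate]) -> BeggResult:
    """Begg-Mazumdar adjusted rank correlation test.

    Effects are standardized against the fixed inverse-variance pooled
    mean (deviates divided by sqrt(v_i - v_pooled)); the Kendall score
    between those deviates and the variances is referred to the normal
    approximation of the tau distribution.
    """
    k = len(effects)
    if k < 3:
        raise InsufficientStudiesError(f"Begg's test needs >= 3 studies, got {k}")
    theta = np.array([e.log_or for e in effects])
    v = np.array([e.se for e in effects]) ** 2
    w = 1.0 / v
    pooled = (w * theta).sum() / w.sum()
    v_pooled = 1.0 / w.sum()
    deviates = (theta - pooled) / np.sqrt(v - v_pooled)

    score = 0
    for i in range(k):
        for j in range(i + 1, k):
            score += int(np.sign(deviates[j] - deviates[i]) * np.sign(v[j] - v[i]))
    n_pairs = k * (k - 1) // 2
    var_score = k * (k - 1) * (2 * k + 5) / 18.0
    z = score / math.sqrt(var_score)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return BeggResult(
        statistic=score / n_pairs, score=score, z=float(z), p_value=p, k=k
    )


def funnel_data(
    effects: Sequence[EffectEstimate],
    se_grid: Sequence[float] | None = None,
) -> FunnelData:
    """One funnel point per study plus pseudo-CI guide lines.

    Guides are mean +/- 1.96*se over ``se_grid`` (default: 50 values
    from 0 to 1.1x the largest observed SE), centred on the fixed
    inverse-variance mean (the effect itself when k = 1).
    """
    points = tuple(
        FunnelPoint(study_label=e.study_label, log_or=e.log_or, se=e.se)
        for e in effects
    )
    if not points:
        return FunnelData(
            points=(),
            center=None,
            guides=pd.DataFrame(columns=["se", "ci_low", "ci_high"]),
        )
    theta = np.array([p.log_or for p in points])
    se = np.array([p.se for p in points])
    w = 1.0 / se**2
    center = float((w * theta).sum() / w.sum())
    if se_grid is None:
        se_grid = np.linspace(0.0, 1.1 * se.max(), 50)
    grid = np.asarray(se_grid, dtype=float)
    guides = pd.DataFrame(
        {
            "se": grid,
            "ci_low": center - Z_95 * grid,
            "ci_high": center + Z_95 * grid,
        }
    )
    return FunnelData(points=points, center=center, guides=guides)


def leave_one_out(
    studies: StudyCollection,
    model: GeneticModel,
    alpha_het: float = 0.05,
    correction: CorrectionPolicy = "haldane",
) -> list[LeaveOneOutRow]:
    """One-way sensitivity analysis: re-pool after deleting each study.

    Model selection (Q-test rule) is re-run on every reduced subset, so
    each row is a complete meta-analysis of the remaining k - 1 studies.
    """
    k = len(studies)
    if k < 3:
        raise InsufficientStudiesError(
            f"leave-one-out needs >= 3 studies so each subset has >= 2, got {k}"
        )
    rows = []
    for study in studies:
        reduced = studies.drop(study.label)
        rows.append(
            LeaveOneOutRow(
                omitted_label=study.label,
                result=select_and_pool(reduced, model, alpha_het, correction),
            )
        )
    return rows
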