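"""Genetic-model contrasts, per-study odds ratios, and Hardy-Weinberg QC.

Each biallelic genotype triple (GG, GA, AA) collapses into a 2x2
case-control table under one of four contrasts; the A-carrying category
is always treated as "exposed" so OR > 1 means the variant allele
increases disease odds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Literal

import pandas as pd
from scipy import stats

from .errors import UndefinedEffectError, ValidationError
from .study_io import GenotypeCounts, Study, StudyCollection

__all__ = [
    "GeneticModel",
    "FourfoldTable",
    "EffectEstimate",
    "HWEResult",
    "build_contingency",
    "log_odds_ratio",
    "study_effect",
    "collection_effects",
    "effects_dataframe",
    "hwe_chi_square",
    "Z_95",
]

#: two-sided 95% normal quantile used for all confidence intervals
Z_95 = 1.959964

CorrectionPolicy = Literal["haldane", "none"]


class GeneticModel(Enum):
    """How the three genotypes collapse into exposed vs unexposed."""

    AA_VS_GG = "AA_vs_GG"  # codominant, GA dropped
    GA_VS_GG = "GA_vs_GG"  # codominant, AA dropped
    DOMINANT = "dominant"  # AA+GA vs GG
    RECESSIVE = "recessive"  # AA vs GA+GG

    @classmethod
    def parse(cls, text: str) -> "GeneticModel":
        aliases = {
            "aa_vs_gg": cls.AA_VS_GG,
            "aa_gg": cls.AA_VS_GG,
            "ga_vs_gg": cls.GA_VS_GG,
            "ga_gg": cls.GA_VS_GG,
            "dominant": cls.DOMINANT,
            "dom": cls.DOMINANT,
            "recessive": cls.RECESSIVE,
            "rec": cls.RECESSIVE,
        }
        key = str(text).strip().lower()
        if key not in aliases:
            raise ValidationError(
                f"unknown genetic model {text!r}; expected one of {sorted(aliases)}"
            )
        return aliases[key]


@dataclass(frozen=True)
class FourfoldTable:
    """2x2 exposed/unexposed x case/control table for one study.

    ``a``/``b`` are exposed cases/controls, ``c``/``d`` unexposed
    cases/controls.  Zero cells are allowed; downstream estimators
    decide how to handle them.
    """

    a: int
    b: int
    c: int
    d: int
    study_label: str = ""

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValidationError(f"cell {name} must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class EffectEstimate:
    """Per-study log odds ratio with its Woolf standard error."""

    log_or: float
    se: float
    study_label: str = ""
    corrected: bool = False

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValidationError(f"standard error must be positive, got {self.se}")
        if not math.isfinite(self.log_or):
            raise ValidationError(f"log odds ratio must be finite, got {self.log_or}")

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            math.exp(self.log_or - Z_95 * self.se),
            math.exp(self.log_or + Z_95 * self.se),
        )


@dataclass(frozen=True)
class HWEResult:
    """Pearson chi-square test (1 df) of Hardy-Weinberg proportions."""

    chi_square: float
    p_value: float
    allele_freq_G: float


def build_contingency(study: Study, model: GeneticModel) -> FourfoldTable:
    """Collapse a study's genotype counts into a 2x2 table under ``model``.

    The A-carrying category is exposed; codominant contrasts drop the
    excluded genotype entirely.
    """
    ca, co = study.cases, study.controls
    if model is GeneticModel.AA_VS_GG:
        a, b, c, d = ca.n_AA, co.n_AA, ca.n_GG, co.n_GG
    elif model is GeneticModel.GA_VS_GG:
        a, b, c, d = ca.n_GA, co.n_GA, ca.n_GG, co.n_GG
    elif model is GeneticModel.DOMINANT:
        a, b = ca.n_GA + ca.n_AA, co.n_GA + co.n_AA
        c, d = ca.n_GG, co.n_GG
    elif model is GeneticModel.RECESSIVE:
        a, b = ca.n_AA, co.n_AA
        c, d = ca.n_GG + ca.n_GA, co.n_GG + co.n_GA
    else:  # pragma: no cover
        raise ValidationError(f"unhandled model {model!r}")
    return FourfoldTable(a=a, b=b, c=c, d=d, study_label=study.label)


def log_odds_ratio(
    table: FourfoldTable, correction: CorrectionPolicy = "haldane"
) -> EffectEstimate:
    """Log odds ratio ln(ad/bc) with Woolf SE sqrt(1/a+1/b+1/c+1/d).

    With ``correction="haldane"`` (default), 0.5 is added to every cell
    when any cell is zero and the ``corrected`` flag is set.  A table
    with an empty margin (no cases, no controls, no exposed or no
    unexposed subjects) has no defined effect regardless of policy.
    """
    a, b, c, d = table.cells()
    if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
        raise UndefinedEffectError(
            f"study {table.study_label!r}: an entire margin of the 2x2 table is zero"
        )
    corrected = False
    cells = [float(x) for x in (a, b, c, d)]
    if min(cells) == 0:
        if correction == "haldane":
            cells = [x + 0.5 for x in cells]
            corrected = True
        else:
            raise UndefinedEffectError(
                f"study {table.study_label!r}: zero cell with correction disabled"
            )
    fa, fb, fc, fd = cells
    return EffectEstimate(
        log_or=math.log(fa * fd / (fb * fc)),
        se=math.sqrt(1 / fa + 1 / fb + 1 / fc + 1 / fd),
        study_label=table.study_label,
        corrected=corrected,
    )


def study_effect(
    study: Study, model: GeneticModel, correction: CorrectionPolicy = "haldane"
) -> EffectEstimate:
    """Convenience: contingency table + log odds ratio in one call."""
    return log_odds_ratio(build_contingency(study, model), correction=correction)


def collection_effects(
    studies: StudyCollection | Iterable[Study],
    model: GeneticModel,
    correction: CorrectionPolicy = "haldane",
) -> list[EffectEstimate]:
    return [study_effect(s, model, correction) for s in studies]


def effects_dataframe(
    studies: StudyCollection,
    models: Iterable[GeneticModel] | None = None,
    correction: CorrectionPolicy = "haldane",
) -> pd.DataFrame:
    """Per-study effect table across models, exportable as delimited text."""
    models = list(models) if models is not None else list(GeneticModel)
    rows = []
    for model in models:
        for study in studies:
            t = build_contingency(study, model)
            e = log_odds_ratio(t, correction=correction)
            lo, hi = e.ci95
            rows.append(
                {
                    "study": study.label,
                    "model": model.value,
                    "a": t.a,
                    "b": t.b,
                    "c": t.c,
                    "d": t.d,
                    "log_or": e.log_or,
                    "se": e.se,
                    "or": e.odds_ratio,
                    "ci_low": lo,
                    "ci_high": hi,
                    "corrected": e.corrected,
                }
            )
    return pd.DataFrame(rows)


def hwe_chi_square(counts: GenotypeCounts) -> HWEResult:
    """Pearson chi-square test of Hardy-Weinberg proportions on one arm.

    The G-allele frequency is estimated as (2*n_GG + n_GA) / (2*n);
    expected counts are (p^2, 2pq, q^2)*n and the statistic is referred
    to chi-square with 1 degree of freedom.  A monomorphic sample has
    nothing to test and returns chi_square 0, p 1.
    """
    n = counts.total
    p = (2 * counts.n_GG + counts.n_GA) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or p == 1.0:
        return HWEResult(chi_square=0.0, p_value=1.0, allele_freq_G=p)
    expected = (p * p * n, 2 * p * q * n, q * q * n)
    chi = sum(
        (obs - exp) ** 2 / exp for obs, exp in zip(counts.as_tuple(), expected)
    )
    return HWEResult(
        chi_square=chi,
        p_value=float(stats.chi2.sf(chi, df=1)),
        allele_freq_G=p,
    )
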