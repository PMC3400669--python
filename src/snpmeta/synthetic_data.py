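"""Simulation of case-control genotype study collections with known truth.

Control genotypes follow Hardy-Weinberg proportions at a drawn A-allele
frequency; case genotype probabilities are tilted by per-genotype odds
ratios, with optional between-study heterogeneity entering as a shared
log-scale shift on both non-reference genotype odds ratios.

Every study derives its own random substream deterministically from the
global seed, so enlarging ``k`` re-uses earlier studies unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .genetic_models import EffectEstimate, GeneticModel
from .study_io import ControlSource, Ethnicity, GenotypeCounts, Study, StudyCollection

__all__ = [
    "SimulationConfig",
    "StudyTruth",
    "SimulationTruth",
    "simulate_collection",
    "simulate_null_funnel",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated collection of case-control studies."""

    k: int = 10
    n_case_range: tuple[int, int] = (200, 600)
    n_control_range: tuple[int, int] = (200, 600)
    allele_freq_A_range: tuple[float, float] = (0.2, 0.5)
    or_GA: float = 1.0
    or_AA: float = 1.0
    tau: float = 0.0
    ethnicity_mix: float = 0.5  # P(Asian); remainder Caucasian
    control_source_mix: float = 0.5  # P(Hospital); remainder Population
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError(f"k must be >= 1, got {self.k}")
        if self.or_GA <= 0 or self.or_AA <= 0:
            raise ValidationError("per-genotype odds ratios must be positive")
        if self.tau < 0:
            raise ValidationError(f"tau must be >= 0, got {self.tau}")
        for name in ("n_case_range", "n_control_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValidationError(f"{name} must be a non-empty range of n >= 1")
        lo, hi = self.allele_freq_A_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValidationError("allele_freq_A_range must lie inside (0, 1)")
        for name in ("ethnicity_mix", "control_source_mix"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class StudyTruth:
    """Generating parameters of one simulated study."""

    label: str
    allele_freq_A: float
    delta: float  # study-level log-OR shift
    control_probs: tuple[float, float, float]
    case_probs: tuple[float, float, float]

    def true_odds_ratio(self, model: GeneticModel) -> float:
        """Odds ratio implied by the generating genotype probabilities."""
        c_gg, c_ga, c_aa = self.case_probs
        k_gg, k_ga, k_aa = self.control_probs
        if model is GeneticModel.AA_VS_GG:
            return (c_aa / c_gg) / (k_aa / k_gg)
        if model is GeneticModel.GA_VS_GG:
            return (c_ga / c_gg) / (k_ga / k_gg)
        if model is GeneticModel.DOMINANT:
            return ((c_ga + c_aa) / c_gg) / ((k_ga + k_aa) / k_gg)
        if model is GeneticModel.RECESSIVE:
            return (c_aa / (c_gg + c_ga)) / (k_aa / (k_gg + k_ga))
        raise ValidationError(f"unhandled model {model!r}")  # pragma: no cover


@dataclass(frozen=True)
class SimulationTruth:
    config: SimulationConfig
    studies: tuple[StudyTruth, ...]


def _study_rng(seed: int, index: int) -> np.random.Generator:
    # substream per study: deterministic in (seed, index) only
    return np.random.default_rng(np.random.SeedSequence((seed, index)))


def simulate_collection(
    config: SimulationConfig,
) -> tuple[StudyCollection, SimulationTruth]:
    """Draw a :class:`StudyCollection` and the truth that generated it.

    Per study: the control A-allele frequency q is uniform on its range;
    control genotype probabilities are the HWE triple (p^2, 2pq, q^2);
    a shift delta ~ Normal(0, tau^2) multiplies both non-reference odds
    ratios; case probabilities are the control triple tilted by
    (1, or_GA*e^delta, or_AA*e^delta) and renormalised; counts are
    multinomial per arm.
    """
    studies: list[Study] = []
    truths: list[StudyTruth] = []
    for i in range(config.k):
        rng = _study_rng(config.seed, i)
        label = f"sim{i + 1:03d}"

        q = float(rng.uniform(*config.allele_freq_A_range))
        p = 1.0 - q
        control_probs = np.array([p * p, 2 * p * q, q * q])
        while control_probs.min() <= 0.0:  # boundary draw: resample
            q = float(rng.uniform(*config.allele_freq_A_range))
            p = 1.0 - q
            control_probs = np.array([p * p, 2 * p * q, q * q])

        delta = float(rng.normal(0.0, config.tau)) if config.tau > 0 else 0.0
        tilt = np.array(
            [1.0, config.or_GA * math.exp(delta), config.or_AA * math.exp(delta)]
        )
        case_probs = control_probs * tilt
        case_probs = case_probs / case_probs.sum()

        n_case = int(rng.integers(config.n_case_range[0], config.n_case_range[1] + 1))
        n_control = int(
            rng.integers(config.n_control_range[0], config.n_control_range[1] + 1)
        )
        case_counts = rng.multinomial(n_case, case_probs)
        control_counts = rng.multinomial(n_control, control_probs)

        ethnicity = (
            Ethnicity.ASIAN
            if rng.uniform() < config.ethnicity_mix
            else Ethnicity.CAUCASIAN
        )
        source = (
            ControlSource.HOSPITAL
            if rng.uniform() < config.control_source_mix
            else ControlSource.POPULATION
        )
        studies.append(
            Study(
                label=label,
                ethnicity=ethnicity,
                control_source=source,
                cases=GenotypeCounts(*(int(x) for x in case_counts)),
                controls=GenotypeCounts(*(int(x) for x in control_counts)),
            )
        )
        truths.append(
            StudyTruth(
                label=label,
                allele_freq_A=q,
                delta=delta,
                control_probs=tuple(control_probs),
                case_probs=tuple(case_probs),
            )
        )
    collection = StudyCollection(
        studies=tuple(studies),
        provenance=f"simulated (seed={config.seed}, k={config.k})",
    )
    return collection, SimulationTruth(config=config, studies=tuple(truths))


def simulate_null_funnel(
    k: int, se_grid: Sequence[float], seed: int
) -> list[EffectEstimate]:
    """Draw k null effects theta_i ~ Normal(0, se_i^2) at the given SEs.

    The SE grid is cycled if shorter than k; used to calibrate the
    Egger and Begg tests against their nominal levels.
    """
    if k < 3:
        raise ValidationError(f"null funnel needs k >= 3, got {k}")
    grid = [float(s) for s in se_grid]
    if not grid or any(s <= 0 for s in grid):
        raise ValidationError("se_grid values must be positive")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xF0)))
    effects = []
    for i in range(k):
        se = grid[i % len(grid)]
        effects.append(
            EffectEstimate(
                log_or=float(rng.normal(0.0, se)), se=se, study_label=f"null{i + 1:03d}"
            )
        )
    return effects
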