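"""End-to-end analysis pipeline: from a study table to the report bundle.

The pipeline adds no computation of its own — every number it emits is
produced by the underlying module operations — it only arranges results
into delimited tables and a structured summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bias_sensitivity import begg_rank_test, egger_test, funnel_data, leave_one_out
from .errors import InsufficientStudiesError, ValidationError
from .genetic_models import (
    CorrectionPolicy,
    GeneticModel,
    collection_effects,
    effects_dataframe,
    hwe_chi_square,
)
from .pooling import (
    PooledResult,
    pool_dersimonian_laird,
    pooled_results_dataframe,
    select_and_pool,
    stratified_analysis,
)
from .study_io import StudyCollection, bundled_fixture, parse_study_table
from .synthetic_data import SimulationConfig, simulate_collection

__all__ = ["RunConfig", "ReportBundle", "load_input", "run_full_analysis",
           "run_simulation_study"]

logger = logging.getLogger("snpmeta")

OVERALL = "Total"

#: CSV float formatting — full double precision, reproducible byte-for-byte
_FLOAT_FMT = "%.12g"


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full analysis run."""

    input_path: str = "fixture"
    models: tuple[GeneticModel, ...] = tuple(GeneticModel)
    stratifiers: tuple[str, ...] = ("ethnicity", "control_source")
    alpha_het: float = 0.05
    correction: CorrectionPolicy = "haldane"
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha_het < 1:
            raise ValidationError(f"alpha_het must lie in (0, 1), got {self.alpha_het}")
        for s in self.stratifiers:
            if s not in ("ethnicity", "control_source"):
                raise ValidationError(f"unknown stratifier {s!r}")


@dataclass
class ReportBundle:
    """All tables produced by one run, plus the structured summary."""

    studies: StudyCollection
    effects: pd.DataFrame
    hwe: pd.DataFrame
    pooled: pd.DataFrame
    bias: pd.DataFrame
    loo: pd.DataFrame
    funnel: pd.DataFrame
    summary: list[dict] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in [
            ("per_study_effects.csv", self.effects),
            ("hwe_qc.csv", self.hwe),
            ("pooled_results.csv", self.pooled),
            ("publication_bias.csv", self.bias),
            ("leave_one_out.csv", self.loo),
            ("funnel_data.csv", self.funnel),
        ]:
            df.to_csv(out / name, index=False, float_format=_FLOAT_FMT)
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(self.summary, fh, indent=2)
        logger.info("report bundle written to %s", out)


def load_input(input_path: str) -> StudyCollection:
    """Resolve the ``fixture`` sentinel or parse a study table file."""
    if input_path == "fixture":
        return bundled_fixture()
    return parse_study_table(input_path)


def _hwe_table(studies: StudyCollection) -> pd.DataFrame:
    rows = []
    for s in studies:
        res = hwe_chi_square(s.controls)
        rows.append(
            {
                "study": s.label,
                "ethnicity": s.ethnicity.value,
                "source": s.control_source.value,
                "n_case": s.n_case,
                "n_control": s.n_control,
                "hwe_chi_square": res.chi_square,
                "hwe_p_value": res.p_value,
                "allele_freq_G_controls": res.allele_freq_G,
                "hwe_flag": res.p_value < 0.05,
            }
        )
    return pd.DataFrame(rows)


def run_full_analysis(config: RunConfig) -> ReportBundle:
    """Run the complete analysis and (optionally) write the report bundle.

    Emits per-study effects, HWE QC, pooled results (overall and per
    stratum x model with the Q-test model-selection rule), Egger/Begg
    publication-bias results, leave-one-out tables, and funnel data.
    """
    studies = load_input(config.input_path)
    if len(studies) < 2:
        raise InsufficientStudiesError(
            f"input {config.input_path!r} parsed into {len(studies)} study(ies); "
            "need >= 2 for pooling"
        )
    logger.info(
        "analysing %d studies (%d cases / %d controls) from %s",
        len(studies), studies.total_cases, studies.total_controls,
        config.input_path,
    )

    effects = effects_dataframe(studies, config.models, config.correction)
    hwe = _hwe_table(studies)

    triples: list[tuple[GeneticModel, str, PooledResult]] = []
    for model in config.models:
        res = select_and_pool(studies, model, config.alpha_het, config.correction)
        logger.info(
            "%s / %s: Q p=%.4f -> %s", OVERALL, model.value,
            res.heterogeneity.p_value, res.method.value,
        )
        triples.append((model, OVERALL, res))
    for stratifier in config.stratifiers:
        for model in config.models:
            for res in stratified_analysis(
                studies, stratifier, model, config.alpha_het, config.correction
            ):
                logger.info(
                    "%s / %s: Q p=%.4f -> %s", res.stratum_label, model.value,
                    res.heterogeneity.p_value, res.method.value,
                )
                triples.append((model, res.stratum_label, res))
    pooled = pooled_results_dataframe(triples)

    bias_rows = []
    funnel_rows = []
    loo_rows = []
    for model in config.models:
        model_effects = collection_effects(studies, model, config.correction)
        if len(model_effects) >= 3:
            egger = egger_test(model_effects)
            begg = begg_rank_test(model_effects)
            bias_rows.append(
                {
                    "model": model.value,
                    "egger_intercept": egger.intercept,
                    "egger_intercept_se": egger.intercept_se,
                    "egger_t": egger.t_statistic,
                    "egger_p_value": egger.p_value,
                    "begg_statistic": begg.statistic,
                    "begg_z": begg.z,
                    "begg_p_value": begg.p_value,
                    "k": egger.k,
                }
            )
            for row in leave_one_out(
                studies, model, config.alpha_het, config.correction
            ):
                res = row.result
                loo_rows.append(
                    {
                        "model": model.value,
                        "omitted": row.omitted_label,
                        "k": res.k,
                        "or": res.or_pooled,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "method": res.method.value,
                        "q_p_value": res.heterogeneity.p_value,
                    }
                )
        fd = funnel_data(model_effects)
        for p in fd.points:
            funnel_rows.append(
                {
                    "model": model.value,
                    "kind": "point",
                    "study": p.study_label,
                    "log_or": p.log_or,
                    "se": p.se,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                }
            )
        for _, g in fd.guides.iterrows():
            funnel_rows.append(
                {
                    "model": model.value,
                    "kind": "guide",
                    "study": "",
                    "log_or": fd.center,
                    "se": g["se"],
                    "ci_low": g["ci_low"],
                    "ci_high": g["ci_high"],
                }
            )

    summary = [
        {k: (v if not isinstance(v, float) or np.isfinite(v) else None)
         for k, v in rec.items()}
        for rec in pooled.to_dict(orient="records")
    ]
    bundle = ReportBundle(
        studies=studies,
        effects=effects,
        hwe=hwe,
        pooled=pooled,
        bias=pd.DataFrame(bias_rows),
        loo=pd.DataFrame(loo_rows),
        funnel=pd.DataFrame(funnel_rows),
        summary=summary,
    )
    if config.out_dir is not None:
        bundle.write(config.out_dir)
    return bundle


def run_simulation_study(
    sim_config: SimulationConfig,
    replicates: int,
    alpha_het: float = 0.05,
    models: Sequence[GeneticModel] = tuple(GeneticModel),
) -> pd.DataFrame:
    """Calibration study: repeated simulate -> analyse cycles.

    For each contrast, reports the mean pooled OR, the coverage of the
    true OR by the 95% CI, the Q-test rejection rate at 0.05, and the
    Egger rejection rate at 0.05, over ``replicates`` replicates.  With
    tau = 0 the true OR per contrast is constant across studies and is
    taken from the first study's truth record.
    """
    if replicates < 1:
        raise ValidationError(f"replicates must be >= 1, got {replicates}")
    stats_acc = {
        m: {"or": [], "covered": 0, "q_reject": 0, "egger_reject": 0, "truth": None}
        for m in models
    }
    for rep in range(replicates):
        cfg = SimulationConfig(
            **{**sim_config.__dict__, "seed": sim_config.seed + rep}
        )
        collection, truth = simulate_collection(cfg)
        for model in models:
            acc = stats_acc[model]
            if acc["truth"] is None:
                acc["truth"] = truth.studies[0].true_odds_ratio(model)
            effects = collection_effects(collection, model)
            res = select_and_pool(collection, model, alpha_het)
            acc["or"].append(res.or_pooled)
            true_or = truth.studies[0].true_odds_ratio(model)
            if res.ci_low <= true_or <= res.ci_high:
                acc["covered"] += 1
            if res.heterogeneity.p_value <= 0.05:
                acc["q_reject"] += 1
            if len(effects) >= 3:
                try:
                    if egger_test(effects).p_value < 0.05:
                        acc["egger_reject"] += 1
                except Exception:
                    pass
    rows = []
    for model in models:
        acc = stats_acc[model]
        rows.append(
            {
                "model": model.value,
                "replicates": replicates,
                "true_or": acc["truth"],
                "mean_pooled_or": float(np.mean(acc["or"])),
                "mean_pooled_log_or": float(np.mean(np.log(acc["or"]))),
                "ci_coverage": acc["covered"] / replicates,
                "q_rejection_rate": acc["q_reject"] / replicates,
                "egger_rejection_rate": acc["egger_reject"] / replicates,
            }
        )
    return pd.DataFrame(rows)
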