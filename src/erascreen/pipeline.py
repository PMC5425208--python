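"""End-to-end assessment runs: read inputs, score, rank, write every table.

The reporting layer does no arithmetic of its own beyond formatting — every
number in every output table is reproducible by calling the module
operations directly. CSVs are written at 3 decimal places for human reading;
a JSON sidecar keeps full precision for regression comparisons.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AssessmentConfig
from .grids import read_exposure_table
from .perceived import aggregate_perceived, compare_rankings
from .risk import RiskResult, compute_risk, rank_within_habitat, rescale_unit_interval
from .survey import applicable_combinations, read_perceived_table, read_survey_table

__all__ = ["run_assessment", "wordcloud_weights", "AssessmentResult"]

logger = logging.getLogger(__name__)

CSV_DECIMALS = 3


@dataclass
class AssessmentResult:
    """Everything one run produces, before any file is written."""

    config: AssessmentConfig
    risk: RiskResult
    top_risk: dict[str, pd.DataFrame]  # habitat_id -> ranked table
    top_effect: dict[str, pd.DataFrame]
    perceived: dict[str, pd.DataFrame]
    comparison: dict[str, pd.DataFrame]
    wordcloud: pd.DataFrame
    log: dict


def wordcloud_weights(total_risks: dict[str, float]) -> pd.DataFrame:
    """Word-cloud weights per threat: total risk, plus a min-max display size.

    No image is rendered — rendering belongs to external tools; the weights
    are the data product (size and colour both scale with total risk).
    """
    if not total_risks:
        raise ValueError("need at least one threat to weight")
    threats = sorted(total_risks, key=lambda t: -total_risks[t])
    weights = np.array([total_risks[t] for t in threats], dtype=float)
    sizes = rescale_unit_interval(weights)
    return pd.DataFrame(
        {"threat_id": threats, "weight": weights, "normalized_size": sizes}
    )


def run_assessment(
    config: AssessmentConfig,
    survey_path,
    exposure_path,
    perceived_path=None,
    responses=None,
    exposure=None,
    perceived_lists=None,
) -> AssessmentResult:
    """Run the full pipeline; inputs may be file paths or in-memory objects."""
    if responses is None:
        responses = read_survey_table(survey_path, config)
    if exposure is None:
        exposure = read_exposure_table(exposure_path)
    if perceived_lists is None and perceived_path is not None:
        perceived_lists = read_perceived_table(perceived_path, config, responses)
    perceived_lists = perceived_lists or {}

    pairs = applicable_combinations(config.threats, config.habitats, exposure)
    result = compute_risk(responses, exposure, config)

    top_risk: dict[str, pd.DataFrame] = {}
    top_effect: dict[str, pd.DataFrame] = {}
    perceived_tables: dict[str, pd.DataFrame] = {}
    comparison: dict[str, pd.DataFrame] = {}
    for h in config.habitats:
        ml_risk = result.risk[
            (result.risk["habitat_id"] == h.id)
            & (result.risk["scenario"] == "most_likely")
        ]
        if not ml_risk.empty:
            top_risk[h.id] = rank_within_habitat(ml_risk, config.top_k)
        ml_eff = result.combined[
            (result.combined["habitat_id"] == h.id)
            & (result.combined["scenario"] == "most_likely")
        ]
        if not ml_eff.empty:
            top_effect[h.id] = rank_within_habitat(
                ml_eff, config.top_k, score_col="effect_combined"
            )
        lists = {
            rid: lst for (rid, hid), lst in perceived_lists.items() if hid == h.id
        }
        if lists:
            scores = aggregate_perceived(lists, h.id, k=config.top_k)
            perceived_tables[h.id] = pd.DataFrame(
                [{"rank": s.rank, "threat_id": s.threat_id, "points": s.points}
                 for s in scores]
            )
            if h.id in top_risk:
                comparison[h.id] = compare_rankings(scores, top_risk[h.id])

    if not result.total_risk.empty:
        cloud = wordcloud_weights(
            dict(zip(result.total_risk["threat_id"], result.total_risk["total_risk"]))
        )
    else:
        cloud = pd.DataFrame(columns=["threat_id", "weight", "normalized_size"])

    log = {
        "responses_read": len(responses),
        "respondents": len({r.respondent_id for r in responses}),
        "applicable_combinations": len(pairs),
        "combinations_with_effect_data": int(
            result.combined[["threat_id", "habitat_id"]].drop_duplicates().shape[0]
        )
        if not result.combined.empty
        else 0,
        "combinations_in_risk": int(
            result.risk[["threat_id", "habitat_id"]].drop_duplicates().shape[0]
        )
        if not result.risk.empty
        else 0,
        "exclusions": result.exclusions["reason"].value_counts().to_dict()
        if not result.exclusions.empty
        else {},
    }
    logger.info("assessment complete: %s", log)
    return AssessmentResult(
        config=config,
        risk=result,
        top_risk=top_risk,
        top_effect=top_effect,
        perceived=perceived_tables,
        comparison=comparison,
        wordcloud=cloud,
        log=log,
    )


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=f"%.{CSV_DECIMALS}f")


def write_outputs(res: AssessmentResult, out_dir) -> list[Path]:
    """Write all result tables under ``out_dir``; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        p = out / name
        _write_csv(df, p)
        written.append(p)

    emit(res.risk.effects, "effect_summaries.csv")
    emit(res.risk.combined, "effect_combined.csv")
    emit(res.risk.uncertainty, "uncertainty.csv")
    emit(res.risk.risk, "risk.csv")
    emit(res.risk.total_risk, "total_risk.csv")
    emit(res.risk.exclusions, "exclusions.csv")
    emit(res.wordcloud, "wordcloud_weights.csv")

    def emit_per_habitat(tables: dict[str, pd.DataFrame], name: str) -> None:
        if not tables:
            return
        df = pd.concat(
            [t.assign(habitat_id=h) for h, t in tables.items()], ignore_index=True
        )
        emit(df, name)

    emit_per_habitat(res.top_risk, "top_risk.csv")
    emit_per_habitat(res.top_effect, "top_effect.csv")
    emit_per_habitat(res.perceived, "perceived_risk.csv")
    emit_per_habitat(res.comparison, "perceived_vs_risk.csv")

    sidecar = {
        "log": res.log,
        "total_risk": res.risk.total_risk.to_dict(orient="records"),
        "risk": res.risk.risk.to_dict(orient="records"),
        "uncertainty": res.risk.uncertainty.to_dict(orient="records"),
    }
    p = out / "results.json"
    p.write_text(json.dumps(sidecar, indent=2, default=float))
    written.append(p)
    (out / "run_log.json").write_text(json.dumps(res.log, indent=2))
    written.append(out / "run_log.json")
    return written
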