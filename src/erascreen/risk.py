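"""Risk scoring: effect aggregation, uncertainty, exposure weighting, ranking.

The scoring chain for each applicable threat-habitat combination is:

1. average the expert scores per indicator and scenario (mean, standard
   error, n);
2. combine the two indicator means into a single effect score per scenario
   (arithmetic mean by default; ``max`` is available for a precautionary
   reading);
3. uncertainty = worst-case mean minus best-case mean, a knowledge-based
   *risk range* retained independently of the risk score — large when the
   scenario scores diverge (e.g. 4 - 1 = 3), zero when experts see no spread
   (2 - 2 = 0);
4. weight the effect score by spatial exposure (effect x spatial_score / 5,
   or x overlap% / 100) for combinations that survive the exposure filter;
5. min-max rescale effect, uncertainty and risk to [0, 1], each over its own
   pooling set, so habitats, threats and scenarios are comparable;
6. rank threats within each habitat by most-likely-scenario risk, and sum
   rescaled risks across habitats into a total score per threat.

Because every step is a mean or a monotone transform, the per-response
scenario ordering (best <= most-likely <= worst) propagates all the way to
the rescaled risk scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grids import ExposureRecord, filter_for_risk
from .survey import INDICATORS, SCENARIOS, SurveyResponse

__all__ = [
    "summarize_effects",
    "combine_indicators",
    "uncertainty_score",
    "weight_by_exposure",
    "rescale_unit_interval",
    "total_threat_risk",
    "rank_within_habitat",
    "top_k_with_ties",
    "compute_risk",
    "RiskResult",
]

logger = logging.getLogger(__name__)


def summarize_effects(responses: Iterable[SurveyResponse]) -> pd.DataFrame:
    """Per (threat, habitat, indicator, scenario): mean score, SE and n.

    The standard error is sample SD / sqrt(n) and is NaN when n = 1 (a
    single response carries no spread information). A respondent who skipped
    a threat simply contributes no row — abstention, not a zero score.
    """
    rows = []
    for resp in responses:
        for (threat_id, indicator), triple in resp.effect_scores.items():
            for scenario in SCENARIOS:
                rows.append(
                    (threat_id, resp.habitat_id, indicator, scenario, triple[scenario])
                )
    if not rows:
        return pd.DataFrame(
            columns=["threat_id", "habitat_id", "indicator", "scenario", "mean", "se", "n"]
        )
    df = pd.DataFrame(
        rows, columns=["threat_id", "habitat_id", "indicator", "scenario", "score"]
    )
    g = df.groupby(["threat_id", "habitat_id", "indicator", "scenario"])["score"]
    out = g.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns="sd")


def combine_indicators(
    e_structure: float | None, e_composition: float | None, mode: str = "mean"
) -> float:
    """Collapse the two indicator means into one effect score.

    If one indicator is missing (no expert scored it) the other is used
    alone, with a warning — dropping the combination would discard real
    signal, and zero-filling would assert "no effect".
    """
    vals = [
        v
        for v in (e_structure, e_composition)
        if v is not None and not (isinstance(v, float) and math.isnan(v))
    ]
    if not vals:
        raise ValueError("both indicators missing; combination has no effect data")
    if len(vals) == 1:
        logger.warning("one effect indicator missing; using the other alone")
        return float(vals[0])
    if mode == "mean":
        return float(np.mean(vals))
    if mode == "max":
        return float(max(vals))
    raise ValueError(f"unknown indicator combination mode {mode!r}")


def uncertainty_score(worst_mean: float, best_mean: float) -> float:
    """Knowledge-based uncertainty: worst-case mean minus best-case mean.

    Non-negativity is guaranteed upstream by the per-response scenario
    ordering and the linearity of the mean; a negative value here means that
    invariant was breached and is a hard error, never clipped.
    """
    diff = worst_mean - best_mean
    if diff < 0:
        raise ValueError(
            f"uncertainty would be negative ({worst_mean} - {best_mean}); "
            "scenario ordering was violated upstream"
        )
    return diff


def weight_by_exposure(
    effect_combined: float,
    spatial_score: int,
    mode: str = "score",
    overlap_percent: float | None = None,
) -> float:
    """Weight an effect score by spatial exposure to get the raw risk score.

    ``score`` mode multiplies by spatial_score / 5 (identity at full
    coverage, order-preserving within a coverage class); ``percent`` mode
    multiplies by overlap_percent / 100 when a computed overlap is available.
    A spatial score of 0 must never reach this point — zero-overlap records
    are removed by the exposure filter.
    """
    if spatial_score == 0:
        raise ValueError("spatial_score 0 reached risk weighting; filter records first")
    if mode == "score":
        return effect_combined * spatial_score / 5.0
    if mode == "percent":
        if overlap_percent is None:
            raise ValueError("percent weighting requires a computed overlap_percent")
        return effect_combined * overlap_percent / 100.0
    raise ValueError(f"unknown weighting mode {mode!r}")


def rescale_unit_interval(scores: Sequence[float]) -> np.ndarray:
    """Min-max rescale a pooled score set to [0, 1].

    The pooling set defines comparability: values rescaled together can be
    compared afterwards. If all scores are equal the transform is degenerate
    and everything maps to 0, with a warning.
    """
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rescale an empty score set")
    lo, hi = np.nanmin(arr), np.nanmax(arr)
    if hi == lo:
        logger.warning("degenerate min-max rescale: all %d scores equal %s", arr.size, lo)
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def total_threat_risk(risk_by_habitat: Mapping[str, float]) -> float:
    """Total risk for one threat: sum of its rescaled per-habitat scores."""
    return float(sum(risk_by_habitat.values()))


def top_k_with_ties(
    items: Sequence, key, k: int, label=None
) -> list[tuple[int, object]]:
    """Competition-rank items descending by ``key``; keep all ties at the cutoff.

    Returns (rank, item) pairs where rank is 1 + the number of items with a
    strictly greater key (so equal keys share a rank, "1224" style). Every
    item whose key equals the k-th ranked value is included, which can make
    the list longer than k. ``label`` orders tied items for display only.
    """
    if k < 1:
        raise ValueError("k must be positive")
    label = label or (lambda x: str(x))
    ordered = sorted(items, key=lambda x: (-key(x), label(x)))
    if not ordered:
        return []
    keys = [key(x) for x in ordered]
    cutoff = keys[min(k, len(ordered)) - 1]
    out = []
    for i, (x, kv) in enumerate(zip(ordered, keys)):
        if kv < cutoff:
            break
        rank = 1 + sum(1 for other in keys if other > kv)
        out.append((rank, x))
    return out


def rank_within_habitat(records: pd.DataFrame, k: int, score_col: str = "risk_rescaled") -> pd.DataFrame:
    """Top-k threats for one habitat by descending score, ties at the cutoff included.

    ``records`` must hold one row per threat for a single habitat and
    scenario (the most-likely scenario for headline rankings).
    """
    items = list(records.itertuples(index=False))
    ranked = top_k_with_ties(
        items, key=lambda r: getattr(r, score_col), k=k, label=lambda r: r.threat_id
    )
    out = pd.DataFrame([r._asdict() for _, r in ranked])
    out.insert(0, "rank", [rank for rank, _ in ranked])
    return out


# ---------------------------------------------------------------------------
# Composed computation


@dataclass
class RiskResult:
    """All tables produced by one risk computation.

    Attributes
    ----------
    effects:
        Per-indicator summaries: threat, habitat, indicator, scenario,
        mean, se, n.
    combined:
        Per combination x scenario: combined effect, its rescaled value, n
        (min over indicators), and the combination's uncertainty score
        (repeated across scenarios for convenience).
    uncertainty:
        Per combination: raw and rescaled uncertainty.
    risk:
        Per risk-eligible combination x scenario: spatial score, quality,
        raw and rescaled risk.
    total_risk:
        Per threat: sum of rescaled most-likely risks over habitats, and the
        number of habitats contributing.
    exclusions:
        Exposure records excluded from risk, with reasons; plus combinations
        flagged "no survey data".
    """

    effects: pd.DataFrame
    combined: pd.DataFrame
    uncertainty: pd.DataFrame
    risk: pd.DataFrame
    total_risk: pd.DataFrame
    exclusions: pd.DataFrame


def _rescale_grouped(df: pd.DataFrame, col: str, pool: str) -> np.ndarray:
    if df.empty:
        return np.array([])
    if pool == "habitat":
        return (
            df.groupby("habitat_id")[col]
            .transform(lambda s: rescale_unit_interval(s.to_numpy()))
            .to_numpy()
        )
    return rescale_unit_interval(df[col].to_numpy())


def compute_risk(
    responses: Sequence[SurveyResponse],
    exposure: Sequence[ExposureRecord],
    config,
) -> RiskResult:
    """Run the full scoring chain from raw responses and exposure records."""
    effects = summarize_effects(responses)

    # Combined effect per (threat, habitat, scenario)
    wide = effects.pivot_table(
        index=["threat_id", "habitat_id", "scenario"],
        columns="indicator",
        values="mean",
        aggfunc="first",
    )
    n_wide = effects.pivot_table(
        index=["threat_id", "habitat_id", "scenario"],
        columns="indicator",
        values="n",
        aggfunc="first",
    )
    combined_rows = []
    for idx, row in wide.iterrows():
        threat_id, habitat_id, scenario = idx
        e_s = row.get(INDICATORS[0])
        e_c = row.get(INDICATORS[1])
        combined_rows.append(
            {
                "threat_id": threat_id,
                "habitat_id": habitat_id,
                "scenario": scenario,
                "effect_combined": combine_indicators(e_s, e_c, config.indicator_mode),
                "n": int(np.nanmin(n_wide.loc[idx].to_numpy())),
            }
        )
    combined = pd.DataFrame(combined_rows)

    exclusion_rows = []

    # Uncertainty per combination, from combined best/worst means
    if not combined.empty:
        cw = combined.pivot_table(
            index=["threat_id", "habitat_id"],
            columns="scenario",
            values="effect_combined",
            aggfunc="first",
        ).reset_index()
        cw["uncertainty"] = [
            uncertainty_score(w, b) for w, b in zip(cw["worst"], cw["best"])
        ]
        uncertainty = cw[["threat_id", "habitat_id", "uncertainty"]].copy()
        uncertainty["uncertainty_rescaled"] = _rescale_grouped(
            uncertainty, "uncertainty", config.rescale_pool
        )
        combined["effect_rescaled"] = _rescale_grouped(
            combined, "effect_combined", config.rescale_pool
        )
        combined = combined.merge(
            uncertainty[["threat_id", "habitat_id", "uncertainty"]],
            on=["threat_id", "habitat_id"],
        )
    else:
        uncertainty = pd.DataFrame(
            columns=["threat_id", "habitat_id", "uncertainty", "uncertainty_rescaled"]
        )

    # Exposure filtering, then risk for survivors with survey data
    kept, excluded = filter_for_risk(exposure)
    for rec, reason in excluded:
        exclusion_rows.append(
            {"threat_id": rec.threat_id, "habitat_id": rec.habitat_id, "reason": reason}
        )

    have_effect = (
        set(map(tuple, combined[["threat_id", "habitat_id"]].itertuples(index=False)))
        if not combined.empty
        else set()
    )
    risk_rows = []
    for rec in kept:
        key = (rec.threat_id, rec.habitat_id)
        if key not in have_effect:
            exclusion_rows.append(
                {"threat_id": rec.threat_id, "habitat_id": rec.habitat_id,
                 "reason": "no survey data"}
            )
            continue
        sub = combined[
            (combined["threat_id"] == rec.threat_id)
            & (combined["habitat_id"] == rec.habitat_id)
        ]
        for _, crow in sub.iterrows():
            risk_rows.append(
                {
                    "threat_id": rec.threat_id,
                    "habitat_id": rec.habitat_id,
                    "scenario": crow["scenario"],
                    "effect_combined": crow["effect_combined"],
                    "uncertainty": crow["uncertainty"],
                    "spatial_score": rec.spatial_score,
                    "quality": rec.quality,
                    "n": crow["n"],
                    "risk_raw": weight_by_exposure(
                        crow["effect_combined"],
                        rec.spatial_score,
                        config.weighting_mode,
                        rec.overlap_percent,
                    ),
                }
            )
    risk = pd.DataFrame(risk_rows)
    if not risk.empty:
        risk["risk_rescaled"] = _rescale_grouped(risk, "risk_raw", config.rescale_pool)
        ml = risk[risk["scenario"] == "most_likely"]
        total = (
            ml.groupby("threat_id")["risk_rescaled"]
            .agg(total_risk="sum", n_habitats="count")
            .reset_index()
            .sort_values("total_risk", ascending=False, ignore_index=True)
        )
    else:
        risk = pd.DataFrame(
            columns=["threat_id", "habitat_id", "scenario", "effect_combined",
                     "uncertainty", "spatial_score", "quality", "n", "risk_raw",
                     "risk_rescaled"]
        )
        total = pd.DataFrame(columns=["threat_id", "total_risk", "n_habitats"])

    exclusions = pd.DataFrame(
        exclusion_rows, columns=["threat_id", "habitat_id", "reason"]
    )
    return RiskResult(
        effects=effects,
        combined=combined,
        uncertainty=uncertainty,
        risk=risk,
        total_risk=total,
        exclusions=exclusions,
    )
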