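"""Domain types and tabular I/O for expert effect-score surveys.

A screening-level ecological risk assessment elicits, for every applicable
threat-habitat combination, three ordinal effect scores per effect indicator:
a best-case, most-likely and worst-case scenario score. Two indicators are
scored: change in physical habitat structure, and change in species
composition and trophic structure. Respondents additionally supply an
ordered, unstructured list of up to five threats they perceive as the
greatest risks to the region (used by :mod:`erascreen.perceived`).

Survey tables are plain CSV. The score file has one row per
respondent x habitat x threat x indicator with columns
``respondent_id, habitat_id, threat_id, indicator, best, most_likely, worst``;
the perceived-risk file has one row per listed threat with columns
``respondent_id, habitat_id, rank, threat_id`` (rank 1 = highest perceived
threat). Validation is strict: unknown identifiers, out-of-scale scores and
scenario-ordering violations (best > most-likely or most-likely > worst) are
hard errors naming the offending rows, because a silent repair would corrupt
the worst-minus-best uncertainty statistic downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "INDICATORS",
    "THREAT_CATEGORIES",
    "Habitat",
    "Threat",
    "ScenarioTriple",
    "SurveyResponse",
    "SurveyValidationError",
    "read_survey_table",
    "write_survey_table",
    "read_perceived_table",
    "write_perceived_table",
    "applicable_combinations",
]

#: The two effect indicators scored in every survey.
INDICATORS = ("physical_structure", "species_composition")

#: Threat source categories used for grouping and display.
THREAT_CATEGORIES = (
    "pollution",
    "aquaculture",
    "fishing",
    "marine habitat modification",
    "coastal HM/activities",
    "climate change",
    "shipping/boating",
    "acid sulfate soil",
    "invasive species",
    "other",
)

SCENARIOS = ("best", "most_likely", "worst")


class SurveyValidationError(ValueError):
    """Raised when a survey table violates the documented contract.

    Carries every offending row so a respondent's file can be fixed in one
    pass rather than error-by-error.
    """

    def __init__(self, message: str, rows: Sequence[int] = ()):
        self.rows = list(rows)
        if self.rows:
            message = f"{message} (rows: {', '.join(map(str, self.rows))})"
        super().__init__(message)


@dataclass(frozen=True)
class Habitat:
    """A risk unit: a marine habitat assessed against every applicable threat."""

    id: str
    name: str
    description: str = ""


@dataclass(frozen=True)
class Threat:
    """A source of risk: a human-mediated activity or process.

    Parameters
    ----------
    category:
        One of :data:`THREAT_CATEGORIES`.
    near_future:
        Anticipated (rather than current) threats are scored for effect but
        excluded from risk because they have no present spatial footprint.
    temporal_category:
        Ordinal 0-5 frequency-of-occurrence class (0 = does not occur,
        5 = near-continuous). A per-pair value in the exposure table takes
        precedence over this default.
    """

    id: str
    name: str
    category: str = "other"
    near_future: bool = False
    temporal_category: int = 5

    def __post_init__(self) -> None:
        if self.category not in THREAT_CATEGORIES:
            raise ValueError(f"unknown threat category {self.category!r}")
        if self.temporal_category not in range(6):
            raise ValueError("temporal_category must be in 0..5")


@dataclass(frozen=True)
class ScenarioTriple:
    """One expert's (best, most-likely, worst) effect scores.

    The ordering best <= most_likely <= worst is an invariant: the
    worst-minus-best difference is the knowledge-uncertainty statistic and
    its sign depends on it.
    """

    best: int
    most_likely: int
    worst: int

    def __post_init__(self) -> None:
        if not (self.best <= self.most_likely <= self.worst):
            raise ValueError(
                f"scenario ordering violated: best={self.best}, "
                f"most_likely={self.most_likely}, worst={self.worst}"
            )

    def validate_scale(self, lo: int, hi: int) -> None:
        for v in (self.best, self.most_likely, self.worst):
            if not (lo <= v <= hi):
                raise ValueError(f"score {v} outside scale [{lo}, {hi}]")

    def __getitem__(self, scenario: str) -> int:
        return getattr(self, scenario)


@dataclass
class SurveyResponse:
    """One expert's completed survey for one habitat."""

    respondent_id: str
    habitat_id: str
    effect_scores: dict[tuple[str, str], ScenarioTriple] = field(default_factory=dict)
    perceived_top5: list[str] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def threats(self) -> set[str]:
        return {t for t, _ in self.effect_scores}


def _check_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SurveyValidationError(
            f"{path}: missing required columns {missing}; found {list(df.columns)}"
        )


def read_survey_table(path, config) -> list[SurveyResponse]:
    """Read a survey score CSV into one ``SurveyResponse`` per respondent x habitat.

    Every row either contributes to exactly one response or raises a named
    error; rows are never silently dropped or repaired.

    Parameters
    ----------
    path:
        CSV with columns ``respondent_id, habitat_id, threat_id, indicator,
        best, most_likely, worst``.
    config:
        :class:`erascreen.config.AssessmentConfig` supplying the habitat and
        threat registries and the score scale bounds.
    """
    df = pd.read_csv(path, dtype=str)
    _check_columns(
        df,
        ["respondent_id", "habitat_id", "threat_id", "indicator", "best", "most_likely", "worst"],
        path,
    )
    habitat_ids = {h.id for h in config.habitats}
    threat_ids = {t.id for t in config.threats}
    lo, hi = config.scale_min, config.scale_max

    bad_id, bad_scale, bad_order = [], [], []
    for i, row in df.iterrows():
        rowno = i + 2  # 1-based plus header, as a user would see it in the file
        if row["habitat_id"] not in habitat_ids or row["threat_id"] not in threat_ids:
            bad_id.append(rowno)
            continue
        if row["indicator"] not in INDICATORS:
            raise SurveyValidationError(
                f"{path}: unknown indicator {row['indicator']!r}", [rowno]
            )
        try:
            b, m, w = (int(row[c]) for c in ("best", "most_likely", "worst"))
        except (TypeError, ValueError):
            bad_scale.append(rowno)
            continue
        if not all(lo <= v <= hi for v in (b, m, w)):
            bad_scale.append(rowno)
        elif not (b <= m <= w):
            bad_order.append(rowno)
    if bad_id:
        raise SurveyValidationError(f"{path}: unknown habitat or threat id", bad_id)
    if bad_scale:
        raise SurveyValidationError(
            f"{path}: score outside scale [{lo}, {hi}] or non-integer", bad_scale
        )
    if bad_order:
        raise SurveyValidationError(
            f"{path}: scenario ordering violated (best <= most_likely <= worst)", bad_order
        )

    responses: dict[tuple[str, str], SurveyResponse] = {}
    for _, row in df.iterrows():
        key = (row["respondent_id"], row["habitat_id"])
        resp = responses.setdefault(
            key, SurveyResponse(respondent_id=key[0], habitat_id=key[1])
        )
        skey = (row["threat_id"], row["indicator"])
        if skey in resp.effect_scores:
            raise SurveyValidationError(
                f"{path}: duplicate score for respondent {key[0]}, habitat {key[1]}, "
                f"threat {skey[0]}, indicator {skey[1]}"
            )
        resp.effect_scores[skey] = ScenarioTriple(
            int(row["best"]), int(row["most_likely"]), int(row["worst"])
        )
    return list(responses.values())


def write_survey_table(responses: Iterable[SurveyResponse], path) -> None:
    """Write responses back to the survey CSV dialect (round-trips with the reader)."""
    rows = []
    for r in responses:
        for (threat_id, indicator), triple in sorted(r.effect_scores.items()):
            rows.append(
                {
                    "respondent_id": r.respondent_id,
                    "habitat_id": r.habitat_id,
                    "threat_id": threat_id,
                    "indicator": indicator,
                    "best": triple.best,
                    "most_likely": triple.most_likely,
                    "worst": triple.worst,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_perceived_table(path, config, responses: Sequence[SurveyResponse] | None = None,
                         strict_threats: bool = False) -> dict[tuple[str, str], list[str]]:
    """Read the perceived top-five CSV into ordered lists per respondent x habitat.

    Threat ids not in the registry are retained with a warning rather than
    dropped (respondents may name threats outside the structured list) unless
    ``strict_threats`` is set. If ``responses`` is given, the lists are also
    attached to the matching ``SurveyResponse`` objects in place.
    """
    import warnings

    df = pd.read_csv(path, dtype=str)
    _check_columns(df, ["respondent_id", "habitat_id", "rank", "threat_id"], path)
    threat_ids = {t.id for t in config.threats}
    lists: dict[tuple[str, str], list[tuple[int, str]]] = {}
    for i, row in df.iterrows():
        rank = int(row["rank"])
        if not 1 <= rank <= 5:
            raise SurveyValidationError(f"{path}: rank must be 1..5", [i + 2])
        if row["threat_id"] not in threat_ids:
            msg = f"{path}: unlisted threat id {row['threat_id']!r} in perceived list"
            if strict_threats:
                raise SurveyValidationError(msg, [i + 2])
            warnings.warn(msg, stacklevel=2)
        lists.setdefault((row["respondent_id"], row["habitat_id"]), []).append(
            (rank, row["threat_id"])
        )
    out: dict[tuple[str, str], list[str]] = {}
    for key, entries in lists.items():
        entries.sort()
        ranks = [r for r, _ in entries]
        if len(set(ranks)) != len(ranks):
            raise SurveyValidationError(
                f"{path}: duplicate rank for respondent {key[0]}, habitat {key[1]}"
            )
        ordered = [t for _, t in entries]
        if len(set(ordered)) != len(ordered):
            raise SurveyValidationError(
                f"{path}: duplicate threat in perceived list for respondent {key[0]}, "
                f"habitat {key[1]}"
            )
        out[key] = ordered
    if responses is not None:
        by_key = {(r.respondent_id, r.habitat_id): r for r in responses}
        for key, ordered in out.items():
            if key in by_key:
                by_key[key].perceived_top5 = ordered
    return out


def write_perceived_table(lists: Mapping[tuple[str, str], Sequence[str]], path) -> None:
    rows = [
        {"respondent_id": rid, "habitat_id": hid, "rank": i + 1, "threat_id": t}
        for (rid, hid), ordered in lists.items()
        for i, t in enumerate(ordered)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def applicable_combinations(threats, habitats, exposure) -> list[tuple[str, str]]:
    """Enumerate the threat-habitat pairs included in the assessment.

    A pair is applicable when an exposure record exists for it and its
    temporal-exposure category is above 0 (the threat actually occurs in the
    habitat). Pairs absent from the exposure table are excluded — absence
    means the threat does not occur there or exposure could not be estimated.
    """
    threat_ids = {t.id for t in threats}
    habitat_ids = {h.id for h in habitats}
    pairs = []
    for rec in exposure:
        if rec.threat_id in threat_ids and rec.habitat_id in habitat_ids:
            if rec.temporal_category > 0:
                pairs.append((rec.threat_id, rec.habitat_id))
    return sorted(set(pairs))
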