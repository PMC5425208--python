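"""Perceived-risk aggregation from unstructured top-five threat lists.

Before scoring threats against a structured framework, each respondent names
the five threats they perceive as greatest, in order. Positional points are
awarded 5 (highest) down to 1 (fifth) and summed per threat within a
habitat — a truncated Borda count. The resulting ranking is deliberately
independent of the score-based risk pipeline; comparing the two is how
perception gaps (threats experts under- or over-weight intuitively) are
surfaced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .risk import top_k_with_ties

__all__ = ["PerceivedScore", "points_from_list", "aggregate_perceived", "compare_rankings"]

MAX_LIST = 5


@dataclass(frozen=True)
class PerceivedScore:
    threat_id: str
    habitat_id: str
    points: int
    rank: int


def points_from_list(ordered_list: Sequence[str], respondent: str = "?") -> dict[str, int]:
    """Positional points for one respondent's ordered list: 5, 4, 3, 2, 1.

    Shorter lists award points from the top — position 1 is always worth 5
    points, anchoring the maximum to "highest ranked threat" regardless of
    how many threats the respondent named.
    """
    if len(ordered_list) > MAX_LIST:
        raise ValueError(f"respondent {respondent}: list longer than {MAX_LIST}")
    if len(set(ordered_list)) != len(ordered_list):
        raise ValueError(f"respondent {respondent}: duplicate threat in top-five list")
    return {t: MAX_LIST + 1 - (i + 1) for i, t in enumerate(ordered_list)}


def aggregate_perceived(
    lists: Mapping[str, Sequence[str]] | Iterable[Sequence[str]],
    habitat_id: str,
    k: int = 5,
) -> list[PerceivedScore]:
    """Sum positional points over respondents and competition-rank the threats.

    ``lists`` maps respondent id to that respondent's ordered list (a bare
    iterable of lists is also accepted). All records tied at the k-th point
    value are included, so the result may exceed k entries.
    """
    if isinstance(lists, Mapping):
        items = lists.items()
    else:
        items = ((str(i), lst) for i, lst in enumerate(lists))
    totals: dict[str, int] = {}
    for respondent, lst in items:
        for threat, pts in points_from_list(lst, respondent).items():
            totals[threat] = totals.get(threat, 0) + pts
    ranked = top_k_with_ties(
        sorted(totals.items()), key=lambda kv: kv[1], k=k, label=lambda kv: kv[0]
    )
    return [
        PerceivedScore(threat_id=t, habitat_id=habitat_id, points=pts, rank=rank)
        for rank, (t, pts) in ranked
    ]


def compare_rankings(
    perceived: Sequence[PerceivedScore], risk_top: pd.DataFrame
) -> pd.DataFrame:
    """Side-by-side table of perceived vs score-based top threats for one habitat.

    ``risk_top`` is the output of :func:`erascreen.risk.rank_within_habitat`.
    Threats appearing in only one ranking get NaN on the other side — those
    rows are the perception gaps.
    """
    p = pd.DataFrame(
        [{"threat_id": s.threat_id, "perceived_rank": s.rank, "points": s.points}
         for s in perceived]
    )
    r = risk_top.rename(columns={"rank": "risk_rank"})[
        ["threat_id", "risk_rank", "risk_rescaled"]
    ]
    if p.empty:
        return r.assign(perceived_rank=pd.NA, points=pd.NA)
    out = p.merge(r, on="threat_id", how="outer")
    return out.sort_values(
        ["perceived_rank", "risk_rank"], na_position="last", ignore_index=True
    )
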