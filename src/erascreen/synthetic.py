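"""Synthetic assessments with known ground truth.

The raw material of a screening-level risk assessment — expert survey
responses and spatial data layers — is study-specific and usually cannot be
redistributed. This module generates both from a known truth, so the whole
pipeline is testable end-to-end and its statistical behaviour (how well mean
scores and rankings recover the underlying consensus at realistic panel
sizes) can be measured.

Response model: each expert's most-likely score is a Gaussian draw around
the true effect with standard deviation ``spread``, rounded half-up to the
discrete scale and clamped to its bounds; the best and worst scores are the
most-likely score minus and plus independent non-negative (half-normal,
rounded) draws with scale ``range_width``, clamped. The scenario ordering
best <= most-likely <= worst therefore holds by construction. This is the
simplest dispersion model that supports standard-error-based recovery
checks; it deliberately omits expert correlation, linguistic uncertainty and
survey fatigue.

``study_conditions`` builds a full-scale synthetic assessment shaped like a
published multi-habitat gulf study: 8 habitats with 15/13/12/11/8/8/8/6
respondents (81 surveys), 38 threats spanning pollution, aquaculture,
fishing, habitat modification, climate change, shipping/boating, acid
sulfate soil and invasive-species categories, three near-future threats and
six threats lacking spatial data (quality 4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import AssessmentConfig
from .grids import BinaryGrid, ExposureRecord, write_ascii_grid, write_exposure_table
from .survey import (
    INDICATORS,
    Habitat,
    ScenarioTriple,
    SurveyResponse,
    Threat,
    write_perceived_table,
    write_survey_table,
)

__all__ = [
    "TruthSpec",
    "generate_responses",
    "generate_perceived_lists",
    "generate_binary_grids",
    "make_fixture",
    "study_conditions",
]


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


@dataclass
class TruthSpec:
    """Ground truth for a synthetic assessment.

    ``true_effect`` maps (threat_id, habitat_id, indicator) to the consensus
    effect the survey is trying to elicit, on the effect scale. ``spread``
    is the between-expert standard deviation of most-likely scores (scale
    units); ``range_width`` is the scale of the half-normal draws separating
    best and worst from most-likely (so the expected worst - best gap grows
    linearly with it).
    """

    true_effect: dict[tuple[str, str, str], float]
    spread: float = 0.8
    range_width: float = 0.8
    seed: int = 0
    scale_min: int = 0
    scale_max: int = 5

    def __post_init__(self) -> None:
        if self.spread < 0 or self.range_width < 0:
            raise ValueError("spread and range_width must be non-negative")
        for key, v in self.true_effect.items():
            if not self.scale_min <= v <= self.scale_max:
                raise ValueError(f"true effect {v} for {key} outside scale bounds")

    def combos(self) -> list[tuple[str, str]]:
        return sorted({(t, h) for t, h, _ in self.true_effect})


def generate_responses(truth: TruthSpec, n_experts: int) -> list[SurveyResponse]:
    """Draw a panel of expert responses from the truth's sampling model.

    Deterministic for a given ``truth.seed``; each expert answers every
    (threat, habitat, indicator) in ``truth.true_effect``, grouped into one
    ``SurveyResponse`` per expert x habitat.
    """
    if n_experts < 1:
        raise ValueError("n_experts must be >= 1")
    rng = np.random.default_rng(truth.seed)
    lo, hi = truth.scale_min, truth.scale_max
    keys = sorted(truth.true_effect)
    mu = np.array([truth.true_effect[k] for k in keys])

    ml = _round_half_up(rng.normal(mu, truth.spread, size=(n_experts, len(keys))))
    ml = np.clip(ml, lo, hi)
    down = _round_half_up(np.abs(rng.normal(0.0, truth.range_width, size=ml.shape))) if truth.range_width > 0 else np.zeros_like(ml)
    up = _round_half_up(np.abs(rng.normal(0.0, truth.range_width, size=ml.shape))) if truth.range_width > 0 else np.zeros_like(ml)
    best = np.clip(ml - down, lo, hi)
    worst = np.clip(ml + up, lo, hi)

    responses: dict[tuple[str, str], SurveyResponse] = {}
    for e in range(n_experts):
        rid = f"expert_{e + 1:02d}"
        for j, (threat_id, habitat_id, indicator) in enumerate(keys):
            resp = responses.setdefault(
                (rid, habitat_id), SurveyResponse(respondent_id=rid, habitat_id=habitat_id)
            )
            resp.effect_scores[(threat_id, indicator)] = ScenarioTriple(
                int(best[e, j]), int(ml[e, j]), int(worst[e, j])
            )
    return list(responses.values())


def generate_perceived_lists(
    truth: TruthSpec, n_experts: int, noise: float = 0.5
) -> dict[tuple[str, str], list[str]]:
    """Per-expert ordered top-five threat lists from noisily perceived truth.

    Each expert ranks the habitat's threats by true effect (averaged over
    indicators) plus Gaussian noise and reports the top five, ties broken by
    threat id. A habitat with fewer than five threats yields shorter lists.
    Seeded independently of :func:`generate_responses` (offset seed) so the
    two draws do not alias.
    """
    if n_experts < 1:
        raise ValueError("n_experts must be >= 1")
    rng = np.random.default_rng(truth.seed + 1)
    by_habitat: dict[str, dict[str, list[float]]] = {}
    for (threat_id, habitat_id, _ind), v in truth.true_effect.items():
        by_habitat.setdefault(habitat_id, {}).setdefault(threat_id, []).append(v)

    out: dict[tuple[str, str], list[str]] = {}
    for habitat_id in sorted(by_habitat):
        threats = sorted(by_habitat[habitat_id])
        means = np.array([np.mean(by_habitat[habitat_id][t]) for t in threats])
        for e in range(n_experts):
            perceived = means + rng.normal(0.0, noise, size=means.size)
            # argsort on (-score, threat_id): descending score, id tie-break
            order = sorted(range(len(threats)), key=lambda i: (-perceived[i], threats[i]))
            out[(f"expert_{e + 1:02d}", habitat_id)] = [threats[i] for i in order[:5]]
    return out


def generate_binary_grids(
    rows: int,
    cols: int,
    habitat_fraction: float,
    overlap_fraction: float,
    seed: int = 0,
    threat_outside_fraction: float = 0.1,
    cell_size: float = 250.0,
) -> tuple[BinaryGrid, BinaryGrid]:
    """Paired habitat/threat presence grids with an exact, known overlap.

    The habitat occupies ``round(habitat_fraction * rows * cols)`` cells;
    the threat covers exactly ``round(overlap_fraction * habitat_cells)`` of
    them plus some cells outside the habitat (so the threat footprint is not
    a subset artefact). Cell placement is random but deterministic under
    ``seed``; counts that cannot be realised on the lattice raise.
    """
    if not 0 < habitat_fraction <= 1:
        raise ValueError("habitat_fraction must be in (0, 1]")
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in [0, 1]")
    n_cells = rows * cols
    n_hab = round(habitat_fraction * n_cells)
    if n_hab < 1:
        raise ValueError("habitat_fraction rounds to zero cells on this lattice")
    n_overlap = round(overlap_fraction * n_hab)
    rng = np.random.default_rng(seed)
    cells = rng.permutation(n_cells)
    hab_cells = cells[:n_hab]
    outside = cells[n_hab:]
    n_out = min(round(threat_outside_fraction * n_cells), outside.size)

    hab = np.zeros(n_cells, dtype=bool)
    hab[hab_cells] = True
    thr = np.zeros(n_cells, dtype=bool)
    thr[rng.choice(hab_cells, size=n_overlap, replace=False)] = True
    if n_out:
        thr[rng.choice(outside, size=n_out, replace=False)] = True
    return (
        BinaryGrid(hab.reshape(rows, cols), cell_size=cell_size),
        BinaryGrid(thr.reshape(rows, cols), cell_size=cell_size),
    )


# ---------------------------------------------------------------------------
# Ready-made assessments


def _truth_for(
    config: AssessmentConfig, rng: np.random.Generator, spread: float, range_width: float, seed: int
) -> TruthSpec:
    true_effect = {
        (t.id, h.id, ind): float(
            np.round(rng.uniform(config.scale_min + 1, config.scale_max - 0.5), 2)
        )
        for h in config.habitats
        for t in config.threats
        for ind in INDICATORS
    }
    return TruthSpec(
        true_effect, spread=spread, range_width=range_width, seed=seed,
        scale_min=config.scale_min, scale_max=config.scale_max,
    )


def make_fixture(
    out_dir,
    n_habitats: int = 3,
    n_threats: int = 6,
    n_experts: int = 8,
    spread: float = 0.8,
    range_width: float = 0.8,
    seed: int = 0,
) -> AssessmentConfig:
    """Emit a complete miniature assessment into ``out_dir``.

    Writes the config (YAML), survey and perceived CSVs, an exposure table
    derived from generated grid pairs, and the grids themselves (ESRI
    ASCII), all in the pipeline's input formats. Returns the config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    habitats = [Habitat(f"hab{i + 1}", f"Habitat {i + 1}") for i in range(n_habitats)]
    threats = [
        Threat(f"thr{i + 1}", f"Threat {i + 1}", category="other")
        for i in range(n_threats)
    ]
    config = AssessmentConfig(habitats=habitats, threats=threats, seed=seed)
    truth = _truth_for(config, rng, spread, range_width, seed)

    responses = generate_responses(truth, n_experts)
    write_survey_table(responses, out / "survey.csv")
    write_perceived_table(
        generate_perceived_lists(truth, n_experts), out / "perceived.csv"
    )

    records = []
    grids_dir = out / "grids"
    grids_dir.mkdir(exist_ok=True)
    for h in habitats:
        hab_frac = rng.uniform(0.1, 0.4)
        for t in threats:
            ov_frac = rng.uniform(0.0, 1.0)
            hab_grid, thr_grid = generate_binary_grids(
                40, 40, hab_frac, ov_frac, seed=int(rng.integers(2**31))
            )
            write_ascii_grid(hab_grid, grids_dir / f"{h.id}.asc")
            write_ascii_grid(thr_grid, grids_dir / f"{t.id}_{h.id}.asc")
            from .grids import exposure_from_grids

            records.append(
                exposure_from_grids(
                    t.id, h.id, hab_grid, thr_grid,
                    quality=int(rng.integers(1, 4)),
                    temporal_category=int(rng.integers(1, 6)),
                )
            )
    write_exposure_table(records, out / "exposure.csv")
    config.to_yaml(out / "config.yaml")
    return config


#: Per-habitat survey counts of the emulated study design (81 in total).
STUDY_SURVEY_COUNTS = {
    "seagrasses": 15,
    "soft_bottom": 13,
    "pelagic": 12,
    "rocky_reef": 11,
    "saltmarshes": 8,
    "intertidal_soft": 8,
    "intertidal_rocky": 8,
    "mangroves": 6,
}

_STUDY_THREATS: list[tuple[str, str, str, bool]] = [
    # (id, name, category, near_future)
    ("nutrient_discharge", "Pollution: nutrient discharge", "pollution", False),
    ("oil_spill", "Pollution: oil spill", "pollution", False),
    ("heavy_metals", "Pollution: heavy metals", "pollution", False),
    ("sediment_dust", "Pollution: sediment & dust", "pollution", False),
    ("brine", "Pollution: brine (desalination)", "pollution", True),
    ("thermal", "Pollution: thermal", "pollution", False),
    ("marine_debris", "Pollution: marine debris", "pollution", False),
    ("urban_stormwater", "Pollution: urban stormwater", "pollution", False),
    ("wastewater", "Pollution: treated wastewater", "pollution", False),
    ("aqua_fish", "Aquaculture: finfish", "aquaculture", False),
    ("aqua_shellfish", "Aquaculture: shellfish", "aquaculture", False),
    ("aqua_landbased", "Aquaculture: land-based discharge", "aquaculture", False),
    ("fish_demersal_trawl", "Fishing: demersal trawl", "fishing", False),
    ("fish_purse_seine", "Fishing: purse seine", "fishing", False),
    ("fish_pots", "Fishing: pots", "fishing", False),
    ("fish_line", "Fishing: line", "fishing", False),
    ("fish_net", "Fishing: net", "fishing", False),
    ("fish_illegal", "Fishing: illegal", "fishing", False),
    ("mhm_dredging", "Marine HM: dredging", "marine habitat modification", True),
    ("mhm_ports", "Marine HM: ports, harbours", "marine habitat modification", False),
    ("mhm_marinas", "Marine HM: marinas, boat ramps", "marine habitat modification", False),
    ("mhm_jetties", "Marine HM: jetties, seawalls", "marine habitat modification", False),
    ("coastal_hm", "Coastal habitat modification", "coastal HM/activities", False),
    ("coastal_activities", "Coastal activities", "coastal HM/activities", False),
    ("cc_warming", "Climate change: global warming", "climate change", False),
    ("cc_acidification", "Climate change: ocean acidification", "climate change", False),
    ("cc_hot_weather", "Climate change: hot weather events", "climate change", False),
    ("cc_sea_level", "Climate change: sea level rise", "climate change", False),
    ("cc_less_rain", "Climate change: decreasing rainfall", "climate change", False),
    ("cc_extreme_rain", "Climate change: extreme rainfall events", "climate change", False),
    ("shipping", "Shipping", "shipping/boating", False),
    ("shipping_high", "Shipping: high level", "shipping/boating", True),
    ("boating", "Boating", "shipping/boating", False),
    ("acid_sulfate", "Acid sulfate soil", "acid sulfate soil", False),
    ("inv_encrusting", "Invasive species: encrusting, fouling", "invasive species", False),
    ("inv_filter", "Invasive species: filter feeders", "invasive species", False),
    ("disease", "Disease outbreaks", "other", False),
    ("habs", "Harmful algal blooms", "other", False),
]

#: Threats carrying data-quality 4 (limited knowledge / no spatial data)
#: in the emulated study conditions.
STUDY_QUALITY4 = (
    "sediment_dust", "cc_sea_level", "disease", "habs", "fish_illegal", "marine_debris",
)

#: Threats with expert-opinion-only spatial evidence (quality 3).
STUDY_QUALITY3 = ("fish_pots", "fish_net", "fish_line", "cc_extreme_rain")


def study_conditions(seed: int = 0, spread: float = 0.8, range_width: float = 0.8):
    """A full-scale synthetic assessment shaped like the emulated study.

    Returns ``(config, truth, responses, perceived_lists, exposure)``:
    8 habitats with 15/13/12/11/8/8/8/6 respondents, 38 threats (so 304
    possible combinations, all with temporal exposure above 0), three
    near-future threats and six quality-4 threats excluded from risk.
    Ubiquitous climate threats get full spatial coverage; other exposures
    are drawn between scores 1 and 5.
    """
    habitat_names = {
        "seagrasses": "Seagrasses", "soft_bottom": "Soft bottom", "pelagic": "Pelagic",
        "rocky_reef": "Rocky reef", "saltmarshes": "Saltmarshes",
        "intertidal_soft": "Intertidal (soft)", "intertidal_rocky": "Intertidal (rocky)",
        "mangroves": "Mangroves",
    }
    habitats = [Habitat(hid, habitat_names[hid]) for hid in STUDY_SURVEY_COUNTS]
    threats = [
        Threat(tid, name, category=cat, near_future=nf)
        for tid, name, cat, nf in _STUDY_THREATS
    ]
    config = AssessmentConfig(habitats=habitats, threats=threats, seed=seed)
    rng = np.random.default_rng(seed)
    truth = _truth_for(config, rng, spread, range_width, seed=int(rng.integers(2**31)))

    responses: list[SurveyResponse] = []
    perceived: dict[tuple[str, str], list[str]] = {}
    for hid, n in STUDY_SURVEY_COUNTS.items():
        sub_truth = TruthSpec(
            {k: v for k, v in truth.true_effect.items() if k[1] == hid},
            spread=spread, range_width=range_width,
            seed=int(rng.integers(2**31)),
            scale_min=config.scale_min, scale_max=config.scale_max,
        )
        hab_resp = generate_responses(sub_truth, n)
        # Distinguish respondent ids across habitats; a real panel shares
        # some experts across habitats but ids only need to be unique here.
        for r in hab_resp:
            r.respondent_id = f"{hid}_{r.respondent_id}"
        responses.extend(hab_resp)
        for (rid, h), lst in generate_perceived_lists(sub_truth, n).items():
            perceived[(f"{hid}_{rid}", h)] = lst

    exposure = []
    for t in threats:
        for h in habitats:
            if t.id in STUDY_QUALITY4:
                quality, score = 4, 0
            elif t.id in STUDY_QUALITY3:
                quality, score = 3, int(rng.integers(1, 6))
            elif t.category == "climate change":
                quality, score = 1, 5  # ubiquitous coverage
            else:
                quality, score = int(rng.integers(1, 3)), int(rng.integers(1, 6))
            exposure.append(
                ExposureRecord(
                    threat_id=t.id, habitat_id=h.id, spatial_score=score,
                    quality=quality, near_future=t.near_future,
                    temporal_category=int(rng.integers(1, 6)),
                )
            )
    return config, truth, responses, perceived, exposure
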