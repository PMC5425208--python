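"""Assessment configuration: scale bounds, registries and pipeline modes."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .survey import Habitat, Threat

__all__ = ["AssessmentConfig"]

WEIGHTING_MODES = ("score", "percent")
INDICATOR_MODES = ("mean", "max")
RESCALE_POOLS = ("assessment", "habitat")


@dataclass
class AssessmentConfig:
    """Everything an assessment run needs beyond the data files themselves.

    Attributes
    ----------
    scale_min, scale_max:
        Bounds of the ordinal effect scale (default 0-5, 0 = no effect).
        All arithmetic downstream is scale-agnostic.
    habitats, threats:
        The registries of risk units and risk sources. Identifiers in the
        survey and exposure tables must resolve against these.
    weighting_mode:
        ``"score"`` multiplies the combined effect by spatial_score / 5;
        ``"percent"`` multiplies by overlap_percent / 100.
    indicator_mode:
        ``"mean"`` (default) or ``"max"`` combination of the two effect
        indicators.
    rescale_pool:
        ``"assessment"`` pools the min-max rescaling over all combinations
        and scenarios jointly (default, for cross-habitat comparability);
        ``"habitat"`` rescales within each habitat.
    top_k:
        Cutoff for top-threat tables; ties at the cutoff are all included.
    """

    scale_min: int = 0
    scale_max: int = 5
    habitats: list[Habitat] = field(default_factory=list)
    threats: list[Threat] = field(default_factory=list)
    weighting_mode: str = "score"
    indicator_mode: str = "mean"
    rescale_pool: str = "assessment"
    top_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale_min >= self.scale_max:
            raise ValueError("scale_min must be below scale_max")
        if self.weighting_mode not in WEIGHTING_MODES:
            raise ValueError(f"weighting_mode must be one of {WEIGHTING_MODES}")
        if self.indicator_mode not in INDICATOR_MODES:
            raise ValueError(f"indicator_mode must be one of {INDICATOR_MODES}")
        if self.rescale_pool not in RESCALE_POOLS:
            raise ValueError(f"rescale_pool must be one of {RESCALE_POOLS}")
        if self.top_k < 1:
            raise ValueError("top_k must be positive")
        for coll, name in ((self.habitats, "habitat"), (self.threats, "threat")):
            ids = [x.id for x in coll]
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate {name} ids in registry")

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["habitats"] = [asdict(h) for h in self.habitats]
        d["threats"] = [asdict(t) for t in self.threats]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AssessmentConfig":
        d = dict(d)
        d["habitats"] = [Habitat(**h) for h in d.get("habitats", [])]
        d["threats"] = [Threat(**t) for t in d.get("threats", [])]
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "AssessmentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    # -- lookups -------------------------------------------------------

    def habitat(self, habitat_id: str) -> Habitat:
        for h in self.habitats:
            if h.id == habitat_id:
                return h
        raise KeyError(habitat_id)

    def threat(self, threat_id: str) -> Threat:
        for t in self.threats:
            if t.id == threat_id:
                return t
        raise KeyError(threat_id)
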