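import numpy as np
import pytest

from erascreen import (
    AssessmentConfig,
    Habitat,
    Threat,
    TruthSpec,
    INDICATORS,
)


@pytest.fixture
def small_config():
    habitats = [Habitat(f"h{i}", f"Habitat {i}") for i in (1, 2, 3)]
    threats = [Threat(f"t{i}", f"Threat {i}") for i in range(1, 6)]
    return AssessmentConfig(habitats=habitats, threats=threats)


@pytest.fixture
def small_truth(small_config):
    rng = np.random.default_rng(42)
    effects = {
        (t.id, h.id, ind): float(np.round(rng.uniform(1.0, 4.0), 2))
        for t in small_config.threats
        for h in small_config.habitats
        for ind in INDICATORS
    }
    return TruthSpec(effects, spread=0.8, range_width=0.8, seed=7)
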