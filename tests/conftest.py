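import numpy as np
import pytest

from vocalearn.discovery import DiscoveryConfig, discover_patterns
from vocalearn.fixtures import CaregiverLanguageSpec
from vocalearn.interaction import (
    SimulatedCaregiver,
    SimulatedCaregiverConfig,
    run_response_session,
)
from vocalearn.synth import ControlFrame, SynthConfig


@pytest.fixture(scope="session")
def synth_config():
    return SynthConfig()


@pytest.fixture(scope="session")
def neutral_vowel_result(synth_config):
    """500 ms neutral vowel with phonation, analyzed throughout the suite."""
    from vocalearn.synth import synthesize

    frames = [ControlFrame(p8_glottal_area=-0.3)] * 100
    return synthesize(frames, synth_config)


@pytest.fixture(scope="session")
def vowel_records():
    """A small seeded vowel-discovery run shared across tests."""
    return discover_patterns(DiscoveryConfig(attention_preset="vowel", seed=11), 4)


@pytest.fixture(scope="session")
def plosive_records():
    return discover_patterns(DiscoveryConfig(attention_preset="plosive", seed=11), 6)


@pytest.fixture(scope="session")
def caregiver_session(vowel_records):
    """Response session of the vowel inventory with an always-on caregiver."""
    patterns = [r.pattern for r in vowel_records]
    cg = SimulatedCaregiver(SimulatedCaregiverConfig(seed=3))
    memory, log = run_response_session(patterns, cg)
    return patterns, memory, log


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
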