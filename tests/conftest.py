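import numpy as np
import pytest

from planexec.synth import (BehaviorConfig, UnitSpec, generate_behavior,
                            generate_session)


@pytest.fixture(scope="session")
def behavior600():
    """Canonical 600 s locomotor-style behavior trace (seed 1)."""
    return generate_behavior(BehaviorConfig(duration=600.0), seed=1)


@pytest.fixture(scope="session")
def behavior120():
    """Short 120 s behavior trace for cheap tests (seed 2)."""
    return generate_behavior(BehaviorConfig(duration=120.0), seed=2)


@pytest.fixture(scope="session")
def behavior300():
    """300 s behavior trace for analyses that need more statistics (seed 5)."""
    return generate_behavior(BehaviorConfig(duration=300.0), seed=5)


@pytest.fixture(scope="session")
def small_session(behavior120):
    """120 s session with six mixed units (planning / execution / sensory)."""
    specs = [
        UnitSpec(lag=-0.5, modulation_sigma=0.2, gain=2.5, baseline_rate=3.0, area="M2"),
        UnitSpec(lag=-0.2, modulation_sigma=0.1, gain=2.5, baseline_rate=3.0, area="M2"),
        UnitSpec(lag=-0.05, modulation_sigma=0.05, gain=2.5, baseline_rate=4.0, area="M1"),
        UnitSpec(lag=0.0, modulation_sigma=0.05, gain=2.5, baseline_rate=4.0, area="M1"),
        UnitSpec(lag=0.2, modulation_sigma=0.1, gain=2.5, baseline_rate=3.0, area="S1"),
        UnitSpec(lag=0.5, modulation_sigma=0.2, gain=2.5, baseline_rate=3.0, area="S1"),
    ]
    return generate_session(behavior120, specs, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
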