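import numpy as np
import pytest

from r2play import (
    EffectConfig,
    ParticipantProfile,
    ProtocolConfig,
    build_protocol,
    simulate_session,
)


@pytest.fixture(scope="session")
def protocol():
    """One deterministic full assessment plan shared across tests."""
    return build_protocol(ProtocolConfig(rng_seed=1))


@pytest.fixture(scope="session")
def layout(protocol):
    return protocol.layout


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def sim_session(protocol):
    """One simulated session with realistic noise, shared read-only."""
    return simulate_session(
        protocol,
        ParticipantProfile(participant_id="FIX", age_years=14.0),
        EffectConfig(noise_cv=0.10),
        np.random.default_rng(7),
    )
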