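"""Shared fixtures.

The two packaged protocols are expensive enough (a few seconds each after
JIT warm-up) that they are run once per session and shared by the
property and acceptance tests.
"""

import pytest

from cardioresp import ScenarioConfig, engine, packaged_scenario


@pytest.fixture(scope="session")
def hf_config():
    return packaged_scenario("hf")


@pytest.fixture(scope="session")
def vad_config():
    return packaged_scenario("hf-vad")


@pytest.fixture(scope="session")
def hf_outcomes(hf_config):
    """HF protocol phases: [rest, peak_exercise]."""
    return engine.run_protocol(hf_config)


@pytest.fixture(scope="session")
def vad_outcomes(vad_config):
    """HF+VAD phases: [rest, peak_exercise, peak_exercise_speed]."""
    return engine.run_protocol(vad_config)


@pytest.fixture(scope="session")
def vad_outcomes_midspeed(vad_config):
    """Same protocol with the final speed step at 10750 rpm instead of
    12000 rpm, for monotonicity-in-speed checks."""
    doc = vad_config.model_dump(mode="json")
    doc["protocol"][-1]["vad_speed"] = 10750.0
    return engine.run_protocol(ScenarioConfig.model_validate(doc))
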