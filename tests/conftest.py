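import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from timegrn.pipeline import run_pipeline
from timegrn.synthetic import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def zero_noise_scenario(tmp_path_factory):
    """A written zero-noise scenario (seed 1) shared across the session."""
    scenario = generate_scenario(ScenarioConfig(seed=1))
    out = tmp_path_factory.mktemp("scenario") / "zero_noise"
    scenario.write(out)
    return scenario, out


@pytest.fixture(scope="session")
def zero_noise_result(zero_noise_scenario):
    scenario, out = zero_noise_scenario
    return scenario, run_pipeline(out)
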