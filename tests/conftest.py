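import pytest

from dsbquant import synthetic
from dsbquant.pipeline import run_scenario_pipeline


@pytest.fixture(scope="session")
def paper_scenario():
    """The default study-emulation array scenario (288 planted hotspots)."""
    return synthetic.build_scenario(preset="paper-emulation", seed=1)


@pytest.fixture(scope="session")
def paper_results(paper_scenario):
    """Full pipeline run (normalize -> scale -> integrate -> calibrate ->
    differential call) over the simulated arrays of the session scenario."""
    return run_scenario_pipeline(paper_scenario)
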