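import pytest
from hypothesis import settings

from norfnet.pipeline import PipelineConfig, run_all

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")
from norfnet.synthetic import SimConfig, simulate

#: gates scaled to the simulated sample count (500 samples; noncanonical
#: ORFs are on in ~45% of them, so pairwise-complete overlaps sit near 100)
SCALED = dict(min_samples=100, min_shared=80)


@pytest.fixture(scope="session")
def sim_default():
    """One default synthetic study, shared read-only across tests."""
    return simulate(SimConfig(seed=7))


@pytest.fixture(scope="session")
def pipeline_result():
    """A full pipeline run on default synthetic data at scaled gates."""
    cfg = PipelineConfig(seed=7, **SCALED)
    return run_all(cfg, run_null=False)
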