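import pytest

from bacpanel import SimulationConfig, Thresholds, run_all, simulate_panel, synthesize
from bacpanel.scoring import LocalAlignmentScorer


@pytest.fixture(scope="session")
def scorer():
    return LocalAlignmentScorer()


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig.small(seed=1)


@pytest.fixture(scope="session")
def small_panel(small_config):
    """In-memory synthetic panel: 9 species in 3 clades, 12 planted SMGC
    families, two spo0B deletions."""
    return synthesize(small_config)


@pytest.fixture(scope="session")
def panel_dir(small_config, tmp_path_factory):
    d = tmp_path_factory.mktemp("panel")
    simulate_panel(small_config, d)
    return d


@pytest.fixture(scope="session")
def pipeline_result(panel_dir, tmp_path_factory):
    """Full pipeline run on the small synthetic panel (shared across tests)."""
    out = tmp_path_factory.mktemp("out")
    return run_all(panel_dir, out, Thresholds(k_clades=3)), out
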