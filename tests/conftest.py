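import pytest

from burnzones.pipeline import PipelineConfig, run_pipeline
from burnzones import synthetic as syn


@pytest.fixture(scope="session")
def sim_config():
    cfg = syn.SimulationConfig()
    cfg.fires.n_fires = 200
    return cfg


@pytest.fixture(scope="session")
def small_world(sim_config):
    """200-fire synthetic world shared across tests (seed 7)."""
    return syn.generate_truth(sim_config, seed=7)


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    cfg = PipelineConfig()
    cfg.simulation.fires.n_fires = 200
    cfg.seed = 7
    workdir = tmp_path_factory.mktemp("pipeline")
    return cfg, run_pipeline(cfg, workdir, use_cache=False)
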