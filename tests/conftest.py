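import pytest

from srnakit.pipeline import PipelineConfig, run_pipeline
from srnakit.synthetic_data import build_reference, default_config

SEED = 11


@pytest.fixture(scope="session")
def sim_config():
    cfg = default_config(seed=SEED)
    cfg.reads_per_library = 8000
    return cfg


@pytest.fixture(scope="session")
def reference(sim_config):
    return build_reference(sim_config, seed=SEED)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, sim_config):
    """One full end-to-end run shared by pipeline and acceptance tests."""
    rundir = tmp_path_factory.mktemp("run")
    cfg = PipelineConfig(seed=SEED)
    cfg.simulation = sim_config
    run_pipeline(rundir, cfg)
    return rundir, cfg
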