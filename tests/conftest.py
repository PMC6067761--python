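import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ruralflux.pipeline import PipelineConfig, run_pipeline
from ruralflux.synthetic import GeneratorConfig, generate_grid

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def demo_dataset():
    """Default ~1,000-cell synthetic dataset, fixed seed."""
    return generate_grid(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """A full pipeline run on the default demo configuration."""
    outdir = tmp_path_factory.mktemp("demo_run")
    config = PipelineConfig(outdir=str(outdir), seed=11)
    manifest = run_pipeline(config)
    return outdir, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
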