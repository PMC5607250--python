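import pytest

from caprimir import SimulationConfig, run_pipeline
from caprimir.synthetic import gen_references


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=3, n_reads_per_library=(20_000, 20_000),
        n_mirnas=20, n_novel_hairpins=4,
    )


@pytest.fixture(scope="session")
def small_result(small_config):
    """One end-to-end run shared by the integration tests."""
    return run_pipeline(small_config)


@pytest.fixture(scope="session")
def small_refs(small_config):
    return gen_references(small_config)
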