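import pytest

from rrlmarkers.pipeline import run_pipeline
from rrlmarkers.simdata import SimConfig


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Desk-scale study design: 300 kb ancestor, 5 founders, both enzymes,
    sequencing errors on."""
    return SimConfig(ancestral_length=300_000, str_count=4, seed=11)


@pytest.fixture(scope="session")
def small_result(small_config):
    return run_pipeline(small_config, analyze=False)


@pytest.fixture(scope="session")
def clean_config() -> SimConfig:
    """Error-free variant of the small design (exact-recovery checks)."""
    return SimConfig(ancestral_length=300_000, str_count=4, error_rate=0.0,
                     seed=13)


@pytest.fixture(scope="session")
def clean_result(clean_config):
    return run_pipeline(clean_config, analyze=False)
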