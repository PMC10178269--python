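import numpy as np
import pytest

from famseg import (
    SimulationConfig,
    load_joined_fixture,
    simulate_family,
)


@pytest.fixture(scope="session")
def fixture_records():
    """The 53 packaged segregating variants with full annotations."""
    return load_joined_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230501)


@pytest.fixture(scope="session")
def small_family():
    """One deterministic simulated family with modest background."""
    cfg = SimulationConfig(n_background_variants=200, seed=42)
    return simulate_family(cfg, np.random.default_rng(42), "FAMX")


def make_trio_ped_text() -> str:
    return (
        "FAM1 F 0 0 1 1\n"
        "FAM1 M 0 0 2 1\n"
        "FAM1 C1 F M 1 2\n"
        "FAM1 C2 F M 2 2\n"
    )
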