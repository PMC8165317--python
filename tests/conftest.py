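import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ribocnv.simulate import GenomeSpec, build_synthetic_genome, demo_ribotype_panel, simulate_reads

settings.register_profile(
    "suite", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")

#: scaled repeat unit used throughout the simulation tests:
#: 18S 300 / ITS1 130 / 5.8S 100 / ITS2 130 / 26S 340 -> U = 1000 bp
SCALED_COMPONENTS = {"18S": 300, "26S": 340}
SCALED_ITS = dict(its1_length=130, r58_length=100, its2_length=130)


def mb_to_pg(mb: float) -> float:
    return mb / 978.0


@pytest.fixture(scope="session")
def scaled_panel():
    return demo_ribotype_panel(0, **SCALED_ITS)


@pytest.fixture(scope="session")
def scaled_genome(scaled_panel):
    spec = GenomeSpec(
        two_c_size_pg=mb_to_pg(4.0),
        native_copy_number=1000,
        foreign_copy_numbers={"panicum": 20},
        unit_components=SCALED_COMPONENTS,
        seed=42,
    )
    return build_synthetic_genome(spec, scaled_panel)


@pytest.fixture(scope="session")
def native_ref(scaled_genome):
    return scaled_genome.native_reference()


@pytest.fixture(scope="session")
def scaled_reads(scaled_genome):
    return simulate_reads(scaled_genome, coverage=1.0, read_length=100, error_rate=0.005, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
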