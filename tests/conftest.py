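import pytest

from faersig.cohort import CohortSpec
from faersig.synthetic import GeneratorConfig, generate

TARGET = "TIOTROPIUM BROMIDE"


@pytest.fixture(scope="session")
def cohort_spec() -> CohortSpec:
    return CohortSpec(name_patterns=("TIOTROPIUM",))


@pytest.fixture(scope="session")
def planted_config() -> GeneratorConfig:
    """Small corpus with two strongly planted drug-event associations."""
    return GeneratorConfig(
        n_cases=5000,
        seed=42,
        planted_associations=(("pt_0001", 6.0), ("pt_0002", 6.0)),
    )


@pytest.fixture(scope="session")
def planted_corpus(planted_config):
    return generate(planted_config)
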