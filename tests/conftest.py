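import pytest

from stpscore import (
    GeneratorConfig,
    calibrate_pathway,
    default_pathway_definitions,
    generate_calibration_set,
    generate_cohort,
    generate_probe_level,
)


@pytest.fixture(scope="session")
def definitions():
    return default_pathway_definitions(25)


@pytest.fixture(scope="session")
def mapk_definition(definitions):
    return next(d for d in definitions if d.pathway_name == "MAPK")


@pytest.fixture(scope="session")
def mapk_model(mapk_definition):
    matrix, labels = generate_calibration_set(
        mapk_definition, n_active=50, n_inactive=50, delta=0.6, sigma=0.3, seed=101
    )
    return calibrate_pathway(matrix, labels, mapk_definition)


@pytest.fixture(scope="session")
def cohort():
    return generate_cohort(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def clean_chip():
    return generate_probe_level(sample_id="chip01", seed=5)
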