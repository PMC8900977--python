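import pytest

from saltsim import pipeline
from saltsim.synthetic_data import (
    GeneratorConfig,
    generate_census,
    generate_fct,
    generate_rate_tables,
    generate_recalls,
)


@pytest.fixture(scope="session")
def gen_config():
    return GeneratorConfig(seed=42)


@pytest.fixture(scope="session")
def census(gen_config):
    return generate_census(gen_config)


@pytest.fixture(scope="session")
def fct():
    return generate_fct()


@pytest.fixture(scope="session")
def recalls(census, fct, gen_config):
    return generate_recalls(census, fct, gen_config)


@pytest.fixture(scope="session")
def rates(gen_config):
    return generate_rate_tables(gen_config)


@pytest.fixture(scope="session")
def inputs():
    """Full prepared model inputs at test scale (2,000 persons)."""
    return pipeline.prepare_inputs(n_persons=2000, seed=7)


@pytest.fixture(scope="session")
def baseline_comparison(inputs):
    """Baseline + one spoon + one substitute scenario under one seed."""
    from saltsim.interventions import ScenarioSpec

    scenarios = [
        ScenarioSpec(kind="none"),
        ScenarioSpec(kind="spoon", spoon_sodium_mg=788.0),
        ScenarioSpec(kind="substitute", substitute_fraction=0.95),
    ]
    return pipeline.compare_scenarios(inputs, scenarios, seed=7)
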