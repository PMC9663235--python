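import pytest
from hypothesis import settings

from sdm import (
    GeneratorSpec,
    fixture_table1,
    fixture_table2,
    generate_kb,
    table3_patient,
)
from sdm.fixtures import IMPEDIMENT_SYNDROME, WAIST_SYNDROME

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def kb_table1():
    return fixture_table1()


@pytest.fixture(scope="session")
def kb_table2():
    return fixture_table2()


@pytest.fixture(scope="session")
def pain_candidates():
    return [WAIST_SYNDROME, IMPEDIMENT_SYNDROME]


@pytest.fixture(scope="session")
def patient3():
    return table3_patient()


@pytest.fixture(scope="session")
def kb_default():
    """Default-condition synthetic base (39 questions, 12 syndromes)."""
    return generate_kb(GeneratorSpec(seed=42))


def small_spec(seed: int, **overrides) -> GeneratorSpec:
    """A small, fast KB shape for seeded sweeps."""
    params = dict(
        n_syndromes=5,
        n_categories=4,
        questions_per_category=3,
        answers_per_question=3,
        symptoms_min=1,
        symptoms_max=3,
        overlap=0.2,
        seed=seed,
    )
    params.update(overrides)
    return GeneratorSpec(**params)
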