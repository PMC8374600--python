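import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from recall24.fixtures import (  # noqa: E402
    GeneratorConfig,
    generate_composition_db,
    generate_equivalence_table,
    worked_recall_fixture,
)


@pytest.fixture(scope="session")
def worked_recall():
    """The 24-entry worked-recall fixture (demo catalogue + transcript)."""
    return worked_recall_fixture()


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(seed=7, n_foods=120, n_recipes=12)


@pytest.fixture(scope="session")
def small_db(small_config):
    return generate_composition_db(small_config)


@pytest.fixture(scope="session")
def eq_fixture():
    """Default-scale grouped equivalence table (100 foods x 16 measures)."""
    return generate_equivalence_table(GeneratorConfig(seed=3))


def vectors_of(eq_fixture, members):
    """Per-member {measure_id: weight} views of a generated group."""
    return {
        m: {mid: float(w) for (fid, mid), w in eq_fixture.table.rows.items() if fid == m}
        for m in members
    }
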