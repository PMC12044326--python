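import pytest

import pbpkddi as p
from pbpkddi.population import Individual


@pytest.fixture(scope="session")
def system():
    return p.default_system()


@pytest.fixture(scope="session")
def library():
    return p.compound_library()


@pytest.fixture(scope="session")
def soticlestat(library):
    return library["soticlestat"]


@pytest.fixture(scope="session")
def nominal_individual(system):
    """A 70-kg reference subject with population-mean physiology."""
    return Individual(id=0, sex="M", age=30.0, body_weight=70.0, system=system)
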