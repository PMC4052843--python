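from __future__ import annotations

import pytest

from strokeaudit import knowledge
from strokeaudit.cohort import generate_cohort


@pytest.fixture(scope="session")
def registry():
    return knowledge.registry()


@pytest.fixture(scope="session")
def store():
    return knowledge.terminology_store()


@pytest.fixture(scope="session")
def guidelines():
    return knowledge.load_guidelines()


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(49)
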