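import logging

import pytest

from sealdisp import datasets
from sealdisp.ingest import SightingRecord

logging.getLogger("sealdisp").setLevel(logging.ERROR)

AN = datasets.ANO_NUEVO
PB = datasets.PIEDRAS_BLANCAS


def rec(animal, birth_colony, birth_year, obs_year, obs_colony):
    return SightingRecord(animal, birth_colony, birth_year, obs_year, obs_colony)


@pytest.fixture(scope="session")
def study_table():
    return datasets.study_cohort_table()


@pytest.fixture(scope="session")
def study_reappearance():
    return datasets.study_reappearance_table()


@pytest.fixture(scope="session")
def study_detection():
    """Moderate-size detection chain shared across tests."""
    return datasets.study_detection_posterior(M=20_000, seed=123)
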