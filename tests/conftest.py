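"""Shared fixtures: the default synthetic study, its feature tables, and a
short injection sequence for fast unit tests.

Heavy objects (full study simulation, feature tables) are session-scoped so
they are computed once per run.
"""

import numpy as np
import pytest

from breathmss import (
    InjectionSequence,
    build_feature_table,
    default_study_config,
    simulate_study,
)
from breathmss.pipeline import metadata_frame

SEED = 123


@pytest.fixture(scope="session")
def study_config():
    return default_study_config(seed=SEED)


@pytest.fixture(scope="session")
def study_records(study_config):
    return simulate_study(study_config)


@pytest.fixture(scope="session")
def study_metadata(study_records):
    return metadata_frame(study_records)


@pytest.fixture(scope="session")
def offset_table(study_records, study_config):
    return build_feature_table(
        study_records, "start_point_offset", sequence=study_config.sequence
    )


@pytest.fixture(scope="session")
def minmax_table(study_records, study_config):
    return build_feature_table(
        study_records, "min_max", sequence=study_config.sequence
    )


@pytest.fixture
def short_sequence():
    """Two 5-s cycles plus six 10-s cycles: enough for T1-T5 at low cost."""
    return InjectionSequence(sampling_rate=100.0, blocks=((5.0, 2), (10.0, 6)))


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
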