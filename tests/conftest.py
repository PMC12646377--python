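from __future__ import annotations

import datetime as dt
import logging
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from fhirpipe import (  # noqa: E402
    ParseResult,
    PipelineConfig,
    SyntheticConfig,
    Task,
    generate_population,
    parse_resources,
)
from fhirpipe._time import UTC  # noqa: E402

logging.getLogger("fhirpipe").setLevel(logging.ERROR)


def ts(year=2021, month=3, day=1, hour=0, minute=0, second=0):
    return dt.datetime(year, month, day, hour, minute, second, tzinfo=UTC)


@pytest.fixture(scope="session")
def small_population():
    """A modest seeded population shared by read-only tests."""
    return generate_population(SyntheticConfig(n_patients=150, seed=13))


@pytest.fixture(scope="session")
def small_parsed(small_population) -> ParseResult:
    return parse_resources(small_population.resources)


@pytest.fixture()
def readmission_config() -> PipelineConfig:
    return PipelineConfig(task=Task.READMISSION, seed=11,
                          split_fractions=(0.7, 0.15, 0.15))
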