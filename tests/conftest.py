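import numpy as np
import pytest

from actinf.experiments import (perisaccadic_analysis, reading_trial,
                                trial_summary, validate_engine,
                                violation_battery)
from actinf.reading import ReadingConfig, build_reading_model


@pytest.fixture(scope="session")
def config():
    return ReadingConfig()


@pytest.fixture(scope="session")
def reading_model(config):
    return build_reading_model(config)


@pytest.fixture(scope="session")
def exemplar_record(config):
    """The exemplar trial: sentence 1, one upper-case (flipped) word."""
    return reading_trial(config, seed=0)


@pytest.fixture(scope="session")
def exemplar_summary(exemplar_record, config):
    return trial_summary(exemplar_record, config)


@pytest.fixture(scope="session")
def violation_records(config):
    return violation_battery(config, seed=0)


@pytest.fixture(scope="session")
def violation_analysis(violation_records):
    return perisaccadic_analysis(violation_records)


@pytest.fixture(scope="session")
def validation_report():
    return validate_engine(n_models=100, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
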