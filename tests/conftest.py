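import numpy as np
import pytest

from spo2former import SimParams, simulate_cohort, simulate_record
from spo2former.records import drop_missing


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_record():
    """A 30-minute noisy record with a moderate apnea burden."""
    return simulate_record(SimParams(duration_s=1800, target_ahi=20, seed=7), patient_id="fix")


@pytest.fixture(scope="session")
def clean_short_record(short_record):
    record, _ = drop_missing(short_record)
    return record


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six 20-minute patients spanning no-OSA to severe."""
    params = SimParams(duration_s=1200, noise_sd=0.3)
    return simulate_cohort(6, [0, 5, 10, 20, 30, 40], params, seed=11)
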