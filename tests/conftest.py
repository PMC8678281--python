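import numpy as np
import pytest

from ctgkit.signal import CTGRecord, FHRSeries, RuleConfig, UCSeries
from ctgkit.simulate import normal_scenario, simulate_scenario


@pytest.fixture(scope="session")
def config():
    return RuleConfig()


@pytest.fixture(scope="session")
def normal_record():
    """One uneventful 35-min labor segment (noise 2 bpm)."""
    record, truth = simulate_scenario(normal_scenario(seed=42))
    return record, truth


def make_flat_record(fhr_bpm=140.0, uc=15.0, minutes=30.0, fs=4.0):
    n = int(round(minutes * 60 * fs))
    return CTGRecord(
        record_id="flat",
        fhr=FHRSeries(0.0, fs, np.full(n, float(fhr_bpm)), np.ones(n, bool)),
        uc=UCSeries(0.0, fs, np.full(n, float(uc))),
    )


@pytest.fixture
def flat_record():
    return make_flat_record()
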