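import numpy as np
import pandas as pd
import pytest

from hrenergetics import synth
from hrenergetics.hrsignal import HeartRateSeries


@pytest.fixture(scope="session")
def spring_profile():
    """72 h spring heart-rate profile with truth track (seed fixed)."""
    return synth.gen_hr_profile("spring", 72, seed=11)


@pytest.fixture(scope="session")
def summer_profile():
    return synth.gen_hr_profile("summer", 72, seed=12)


@pytest.fixture()
def constant_series():
    """Factory: flat heart-rate series at a given rate and length."""

    def make(bpm: float, n_min: int = 120, start="2020-04-10T05:00:00Z") -> HeartRateSeries:
        ts = pd.date_range(pd.Timestamp(start), periods=n_min, freq="min")
        return HeartRateSeries(
            pd.DataFrame(
                {"timestamp": ts, "hr_bpm": float(bpm), "quality": 1.0, "source": "auto"}
            )
        )

    return make
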