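import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from microconc import CaseSeries, generate_network

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_network():
    """A 12-segment / 6-intersection jittered grid."""
    return generate_network(12, 6, seed=7)


def make_series(microplace_ids, years=None, dates=None):
    """Build a CaseSeries from a list of microplace ids (and years)."""
    n = len(microplace_ids)
    if dates is None:
        years = years if years is not None else [2007] * n
        dates = [pd.Timestamp(year=y, month=6, day=1) + pd.Timedelta(days=i)
                 for i, y in enumerate(years)]
    return CaseSeries(
        pd.DataFrame(
            {
                "event_id": [f"e{i:04d}" for i in range(n)],
                "date": dates,
                "microplace_id": microplace_ids,
                "assignment_distance": 0.0,
            }
        )
    )


@pytest.fixture()
def series_factory():
    return make_series
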