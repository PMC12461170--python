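import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from shadowzone.grid_coverage import build_grid
from shadowzone.rtls_io import PositionStream

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

T0 = pd.Timestamp("2024-08-04 00:00:00", tz="UTC")


@pytest.fixture
def t0():
    return T0


@pytest.fixture
def grid20():
    return build_grid((20.0, 20.0))


@pytest.fixture
def mk_stream():
    """Build a PositionStream from (tag_id, seconds, x, y) tuples."""

    def build(records):
        tags, secs, xs, ys = zip(*records)
        df = pd.DataFrame(
            {
                "tag_id": [str(t) for t in tags],
                "t": T0 + pd.to_timedelta(np.asarray(secs, float), unit="s"),
                "x": np.asarray(xs, float),
                "y": np.asarray(ys, float),
            }
        )
        return PositionStream.from_dataframe(df)

    return build


@pytest.fixture
def shadow_oracle():
    """Full-history windowed-scan shadow oracle.

    A cell is in shadow at frame t iff the last T coverage rasters (a full
    window; partial start-of-stream windows never qualify) are all uncovered.
    Independent of the incremental counter implementation.
    """

    def oracle(cov, T):
        n = cov.shape[0]
        out = np.zeros_like(cov, dtype=bool)
        for t in range(n):
            if t + 1 >= T:
                out[t] = ~cov[t - T + 1 : t + 1].any(axis=0)
        return out

    return oracle
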