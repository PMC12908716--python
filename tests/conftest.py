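import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from fieldgaze.records import GeoTrack
from fieldgaze.synthetic_data import WalkScenario, write_synthetic_session

settings.register_profile(
    "fieldgaze",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fieldgaze")


@pytest.fixture
def simple_track():
    """1 Hz, 10-fix track moving due north at 3.6 km/h, clean metadata."""
    n = 10
    t = np.arange(n, dtype=float)
    lat = 34.670 + np.degrees(1.0 * t / 6_371_000.0)  # 1 m/s northward
    return GeoTrack(
        pd.DataFrame(
            {
                "t": t,
                "lat": lat,
                "lon": np.full(n, 33.040),
                "quality": 1.0,
                "n_satellites": 10.0,
                "precision": np.nan,
            }
        )
    )


@pytest.fixture(scope="session")
def synthetic_session_dir(tmp_path_factory):
    """A full materialized synthetic session, shared across tests."""
    out = tmp_path_factory.mktemp("session")
    scenario = WalkScenario(seed=11, duration_s=200.0, clock_offset_s=6.4)
    manifest_path = write_synthetic_session(out, scenario, session_id="1_1")
    return manifest_path
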