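from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from reefrange import synthetic_data
from reefrange.detections_core import StudyWindow, utc_offset_tz

TZ = utc_offset_tz()


def dt(*args) -> datetime:
    return datetime(*args, tzinfo=TZ)


def make_dets(rows) -> pd.DataFrame:
    """rows: iterable of (datetime, tag_id, station_id)."""
    df = pd.DataFrame(rows, columns=["timestamp", "tag_id", "station_id"])
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).dt.tz_convert(TZ)
    return df


@pytest.fixture(scope="session")
def default_sim():
    """The canonical study-condition simulation: 30 fish, 60 days, ring
    array, injected false detections, emigrants."""
    return synthetic_data.simulate(synthetic_data.SimConfig(seed=20101102))


@pytest.fixture(scope="session")
def default_recovery(default_sim):
    return synthetic_data.truth_check(default_sim)


@pytest.fixture(scope="session")
def small_sim():
    """A light simulation for plumbing tests."""
    cfg = synthetic_data.SimConfig(seed=7, n_fish=4, study_days=8,
                                   false_detection_rate_per_day=1.0)
    return synthetic_data.simulate(cfg)


@pytest.fixture()
def window_2011():
    return StudyWindow(date(2010, 11, 4), date(2011, 10, 31),
                       [(date(2011, 4, 15), date(2011, 5, 13))])
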