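import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import herdrank as hr

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def message_csv(rows):
    """Build an in-memory message-log CSV from (serial, ts, lat, lon, type) rows."""
    buf = io.StringIO()
    buf.write("serial,timestamp,lat,lon,msg_type\n")
    for r in rows:
        buf.write(",".join(str(v) for v in r) + "\n")
    buf.seek(0)
    return buf


def make_median_table(n_cows, n_days, intervals_per_day, rng,
                      start="2023-08-15"):
    """Interval median-distance table with random distinct distances."""
    days = pd.date_range(start, periods=n_days).date
    rows = pd.MultiIndex.from_product(
        [days, range(intervals_per_day), range(n_cows)],
        names=["day", "interval_index", "cow"],
    ).to_frame(index=False)
    return pd.DataFrame(
        {
            "day": rows["day"],
            "interval_index": rows["interval_index"],
            "cow_id": [f"Cow{c + 1:02d}" for c in rows["cow"]],
            "median_distance_m": rng.uniform(10.0, 500.0, len(rows)),
            "n_present": n_cows,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230815)


@pytest.fixture(scope="session")
def small_sim():
    """A small complete herd: 6 animals, 6 days, hourly cadence."""
    cfg = hr.SimConfig(n_cows=6, n_days=6, intervals_per_day=24,
                       dropout_prob=0.0, seed=7)
    return hr.simulate_message_log(cfg)


@pytest.fixture(scope="session")
def small_intervals(small_sim):
    mapped = hr.apply_collar_map(
        _records_from(small_sim), hr.CollarMap(small_sim.collar_map)
    )
    return hr.bin_15min(mapped.records)


def _records_from(sim):
    df = sim.messages.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df
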