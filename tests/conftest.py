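import numpy as np
import pandas as pd
import pytest

from rootdyn.records import ImagingSchedule, IntervalCensoredSet, RootObservationSet


@pytest.fixture
def schedule():
    return ImagingSchedule(
        session_days=np.array([0, 21, 42, 63, 84, 105]),
        seasons={"GS": (0, 105)},
    )


@pytest.fixture
def three_root_table():
    """Three roots: one dies, one disappears without dead, one censored."""
    rows = []

    def add(rid, cls, statuses, lengths):
        for day, st, ln in zip([0, 21, 42, 63, 84, 105], statuses, lengths):
            rows.append(("sd1" if rid != "r3" else "sd2", rid, st, ln, day, cls))

    add("r1", "short",
        ["absent", "live", "live", "dead", "dead", "disappeared"],
        [0.0, 0.010, 0.015, 0.0, 0.0, 0.0])
    add("r2", "short",
        ["live", "live", "disappeared", "disappeared", "disappeared", "disappeared"],
        [0.005, 0.007, 0.0, 0.0, 0.0, 0.0])
    add("r3", "long",
        ["absent", "absent", "live", "live", "live", "live"],
        [0.0, 0.0, 0.020, 0.022, 0.024, 0.025])
    df = pd.DataFrame(
        rows, columns=["seedling_id", "root_id", "status", "length_m", "session_day", "root_class"]
    )
    df["treatment"] = np.where(df["seedling_id"] == "sd1", "Cool", "Warm")
    return df


@pytest.fixture
def three_root_set(three_root_table):
    return RootObservationSet(three_root_table)


def grid_censor(times, step=21.0, end=630.0):
    """Observe exact event times on an imaging grid: death in (k*step,
    (k+1)*step]; right-censored at the last session before ``end``."""
    times = np.asarray(times, dtype=float)
    k = np.floor(times / step)
    cen = times >= end
    left = np.where(cen, np.floor(end / step) * step, k * step)
    right = np.where(cen, np.inf, (k + 1) * step)
    return left, right


def make_interval_set(left, right, groups=None):
    left = np.asarray(left, dtype=float)
    if groups is None:
        groups = np.array(["all"] * left.size)
    return IntervalCensoredSet(np.arange(left.size), np.asarray(groups), left, right)
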