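import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

from damsleep.damio import ActivitySeries, LightSchedule, annotate_photoperiod

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")

T0 = dt.datetime(2024, 1, 1, 8, 0)  # lights-on at 08:00


@pytest.fixture
def ld_schedule():
    return LightSchedule(lights_on=dt.time(8, 0))


@pytest.fixture
def dd_schedule():
    """5 LD days then release into constant darkness."""
    return LightSchedule(
        lights_on=dt.time(8, 0),
        dd_start=T0 + dt.timedelta(days=5),
    )


@pytest.fixture
def make_series(ld_schedule):
    """Factory: a 1-min annotated series starting at lights-on."""

    def _make(counts, schedule=None, **kwargs):
        s = ActivitySeries(
            fly_id=kwargs.pop("fly_id", "test#01"),
            monitor_id="test",
            channel=kwargs.pop("channel", 1),
            group_label=kwargs.pop("group_label", "g"),
            bin_width=kwargs.pop("bin_width", 1),
            t0=kwargs.pop("t0", T0),
            counts=np.asarray(counts),
            **kwargs,
        )
        return annotate_photoperiod(s, schedule or ld_schedule)

    return _make


@pytest.fixture(scope="session")
def sim_fly():
    """One rhythmic simulated fly: 5 LD + 8 DD days, tau = 23.5 h."""
    from damsleep.synthetic import GroupSpec, simulate_fly

    schedule = LightSchedule(
        lights_on=dt.time(8, 0), dd_start=T0 + dt.timedelta(days=5)
    )
    spec = GroupSpec(label="sim", tau_hours=23.5)
    return simulate_fly(spec, schedule, 13, seed=42, t0=T0)
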