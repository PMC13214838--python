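import warnings

import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from circalux import CircadianParams, SleepParams
from circalux.engine import SimulationResult, equilibrate
from circalux.protocols import LightSchedule


@pytest.fixture(scope="session")
def default_cparams():
    return CircadianParams()


@pytest.fixture(scope="session")
def default_sparams():
    return SleepParams()


@pytest.fixture(scope="session")
def equilibration_run(default_cparams, default_sparams):
    """Shared 30-day run on the regular 16:8 1000-lux schedule."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cs, ss, res = equilibrate(default_cparams, default_sparams, return_result=True)
    return cs, ss, res


@pytest.fixture(scope="session")
def dark_schedule_40d():
    return LightSchedule(np.array([[0.0, 24.0 * 40, 0.0, 0.0]]), 40, "dark-40d")


def make_fake_result(
    t_end_h=48.0,
    episodes=(),
    event_times=(),
    cbt_min=(),
    cparams=None,
    sparams=None,
    dt=0.5,
):
    """Minimal hand-built SimulationResult for metric-level tests."""
    from circalux.engine import SleepEpisode

    t = np.arange(0.0, t_end_h + 1e-9, dt)
    eps = [SleepEpisode(a, b, bool(f)) for a, b, f in episodes]
    asleep = np.zeros_like(t, dtype=bool)
    for ep in eps:
        asleep |= (t >= ep.onset_h) & (t < ep.offset_h)
    ev_t = np.asarray(sorted(event_times), dtype=float)
    cbt = np.asarray(cbt_min, dtype=float)
    return SimulationResult(
        t=t,
        x=np.cos(2 * np.pi * (t - 16.5) / 24.0),
        x_c=np.sin(2 * np.pi * (t - 16.5) / 24.0),
        n=np.zeros_like(t),
        H=np.full_like(t, 10.0),
        asleep=asleep,
        sleep_episodes=eps,
        event_times=ev_t,
        event_kinds=np.zeros(len(ev_t), dtype=np.int8),
        cbt_min_series=cbt,
        dlmo_series=cbt - 7.0,
        schedule_label="fake",
        cparams=cparams or CircadianParams(),
        sparams=sparams or SleepParams(),
    )
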