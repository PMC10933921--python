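import numpy as np
import pytest

from linerslip.simulate import SimulationConfig, VacuumTrace


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


def make_trace(vacuum, fs=200.0, airbleed=None, observation_id="synthetic"):
    """Build a VacuumTrace from a vacuum sample array (test helper)."""
    vacuum = np.asarray(vacuum, dtype=float)
    n = len(vacuum)
    if airbleed is None:
        airbleed = np.full(n, 40.0)
    return VacuumTrace(
        time_s=np.arange(n) / fs,
        smt_vacuum_kpa=vacuum,
        airbleed_index=np.asarray(airbleed, dtype=float),
        observation_id=observation_id,
    )


def ramp_trace(level=45.0, drop_kpa=21.0, drop_duration_s=0.2, fs=200.0,
               pre_s=4.0, hold_s=0.3, recover_s=1.0, post_s=4.0):
    """Flat trace with one linear vacuum drop, a hold, and a linear recovery."""
    t_total = pre_s + drop_duration_s + hold_s + recover_s + post_s
    n = int(round(t_total * fs))
    t = np.arange(n) / fs
    v = np.full(n, level)
    t0 = pre_s
    t1 = pre_s + drop_duration_s
    t2 = t1 + hold_s
    t3 = t2 + recover_s
    drop = (t >= t0) & (t < t1)
    v[drop] = level - drop_kpa * (t[drop] - t0) / drop_duration_s
    v[(t >= t1) & (t < t2)] = level - drop_kpa
    rec = (t >= t2) & (t < t3)
    v[rec] = level - drop_kpa * (1 - (t[rec] - t2) / recover_s)
    return make_trace(v, fs=fs)


def overlap(a_start, a_end, b_start, b_end, tol=1.0):
    return a_start < b_end + tol and a_end > b_start - tol


def match_events(detected, truth, tol=1.0):
    """Recall/precision of detected event intervals against ground truth."""
    tp = sum(
        1 for ev in truth
        if any(overlap(d.start_s, d.end_s, ev.start_s, ev.end_s, tol) for d in detected)
    )
    fp = sum(
        1 for d in detected
        if not any(overlap(d.start_s, d.end_s, ev.start_s, ev.end_s, tol) for ev in truth)
    )
    return tp, len(truth) - tp, fp
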