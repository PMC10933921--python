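"""Rule-based liner-slip detection on vacuum and air-bleed traces.

Three detection procedures operate on a :class:`~linerslip.simulate.VacuumTrace`:

* the milk-meter rule (:func:`detect_meter_slip`): a binary flag raised
  when the 0-255 air-bleed index stays strictly above a slip limit for at
  least a minimum duration (default 175 / 30 s);
* irregular-vacuum-fluctuation detection
  (:func:`detect_irregular_fluctuations`): events where the short-milk-tube
  vacuum descends by at least a magnitude threshold at a descent rate of at
  least a rate threshold (type 1: 100 kPa/s and 21 kPa; type 2: 56 kPa/s
  and 14 kPa), after removing a slow moving-median baseline so the
  pulsation-locked cyclic fluctuation and the flow trend do not trigger
  the magnitude test;
* stochastic audible-observer emulation (:func:`detect_observer`).

Plus rule-based milking-phase segmentation (:func:`segment_phases`) and
the average cyclic vacuum summary (:func:`avg_cyclic_vacuum`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .simulate import (
    OVERMILKING_MARGIN_KPA,
    OVERMILKING_REF_OFFSET_S,
    PHASE_BEGIN,
    PHASE_END,
    PHASE_MID,
    MilkingPhases,
    SlipEvent,
    VacuumTrace,
    observer_hears,
)

__all__ = [
    "MeterRule",
    "FluctuationRule",
    "TYPE1_RULE",
    "TYPE2_RULE",
    "DEFAULT_METER_RULE",
    "ObserverWindow",
    "detect_meter_slip",
    "detect_irregular_fluctuations",
    "classify_slp_v",
    "detect_observer",
    "segment_phases",
    "avg_cyclic_vacuum",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MeterRule:
    """Milk-meter air-bleed rule: strictly above ``slip_limit`` for at
    least ``min_duration_s`` seconds."""

    slip_limit: float = 175.0
    min_duration_s: float = 30.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.slip_limit <= 255.0:
            raise ValueError("slip_limit must lie in [0, 255]")
        if self.min_duration_s <= 0:
            raise ValueError("min_duration_s must be > 0")


@dataclass(frozen=True)
class FluctuationRule:
    """Irregular-vacuum-fluctuation thresholds (descent rate and magnitude)."""

    drop_rate_kpa_s: float
    magnitude_kpa: float
    name: str

    def __post_init__(self) -> None:
        if self.drop_rate_kpa_s <= 0 or self.magnitude_kpa <= 0:
            raise ValueError("both thresholds must be > 0")


TYPE1_RULE = FluctuationRule(drop_rate_kpa_s=100.0, magnitude_kpa=21.0, name="type1")
TYPE2_RULE = FluctuationRule(drop_rate_kpa_s=56.0, magnitude_kpa=14.0, name="type2")
DEFAULT_METER_RULE = MeterRule()


@dataclass(frozen=True)
class ObserverWindow:
    """Fraction of the unit-on time covered by one audible observer."""

    observer_id: int
    start_frac: float
    end_frac: float

    def __post_init__(self) -> None:
        if self.observer_id not in (1, 2, 3):
            raise ValueError("observer_id must be 1, 2 or 3")
        if not 0.0 <= self.start_frac < self.end_frac <= 1.0:
            raise ValueError("need 0 <= start_frac < end_frac <= 1")


DEFAULT_OBSERVER_WINDOWS = (
    ObserverWindow(1, 0.0, 0.25),
    ObserverWindow(2, 0.25, 0.85),
    ObserverWindow(3, 0.85, 1.0),
)


# ---------------------------------------------------------------------------
# Milk-meter rule


def detect_meter_slip(trace: VacuumTrace, rule: MeterRule = DEFAULT_METER_RULE) -> int:
    """Binary milk-meter slip flag.

    Present (1) iff some run of consecutive samples with air-bleed index
    strictly above ``rule.slip_limit`` spans at least ``rule.min_duration_s``
    (run length x sampling step, inclusive).  Like the physical device,
    only the binary outcome is reported, not when or how often.
    """
    n = len(trace.time_s)
    if n == 0:
        return 0
    dt = 1.0 / trace.sampling_rate_hz if n >= 2 else 0.0
    if n * dt < rule.min_duration_s:
        logger.warning(
            "trace %s shorter (%.1f s) than the meter minimum duration (%.1f s)",
            trace.observation_id, n * dt, rule.min_duration_s,
        )
        return 0
    above = trace.airbleed_index > rule.slip_limit
    if not above.any():
        return 0
    # run lengths of consecutive True
    padded = np.concatenate([[0], above.astype(np.int8), [0]])
    edges = np.diff(padded)
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    longest = int((ends - starts).max())
    return int(longest * dt >= rule.min_duration_s - 1e-12)


# ---------------------------------------------------------------------------
# Irregular vacuum fluctuations


def _odd(k: int) -> int:
    return k if k % 2 == 1 else k + 1


def _rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    if len(x) <= window:
        return np.full_like(x, np.median(x))
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).median().to_numpy()
    )


def _trailing_median(x: np.ndarray, window: int) -> np.ndarray:
    if len(x) <= window:
        return np.full_like(x, np.median(x))
    return pd.Series(x).rolling(window, min_periods=1).median().to_numpy()


def _movmean(x: np.ndarray, window: int) -> np.ndarray:
    return pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()


def _max_descent_rate(s: np.ndarray, dt: float, min_lag: int, max_lag: int) -> float:
    """Steepest descent (kPa/s) over lags in [min_lag, max_lag] samples."""
    n = len(s)
    best = 0.0
    for lag in range(min_lag, min(max_lag, n - 1) + 1):
        drops = s[:-lag] - s[lag:]
        m = drops.max() / (lag * dt)
        if m > best:
            best = float(m)
    return best


@dataclass
class _Candidate:
    i_start: int
    i_end: int
    magnitude: float
    rate: float


def _candidate_events(trace: VacuumTrace, *, baseline_window_s: float,
                      smooth_s: float, slope_window_s: float,
                      merge_gap_s: float,
                      candidate_prominence_kpa: float) -> list[_Candidate]:
    """Rule-independent slip candidates with measured magnitude and rate.

    Candidates are merged into clusters (gap < ``merge_gap_s``) before any
    thresholding, so stricter rules always select a subset of the clusters
    a looser rule selects.
    """
    v = trace.smt_vacuum_kpa
    n = len(v)
    if n < 4:
        return []
    fs = trace.sampling_rate_hz
    dt = 1.0 / fs
    # trailing median: a centred window would anticipate the slip (the
    # window is majority-slip from the onset for events longer than half
    # the window, erasing the residual drop); the light mean removes the
    # median's step discontinuities so baseline jumps cannot masquerade as
    # rapid descents
    base = _trailing_median(v, _odd(max(int(round(baseline_window_s * fs)), 3)))
    base = _movmean(base, _odd(max(int(round(1.0 * fs)), 3)))
    r = v - base
    smooth_w = _odd(max(int(round(smooth_s * fs)), 3))
    s = _movmean(r, smooth_w)

    troughs, _props = find_peaks(-s, prominence=candidate_prominence_kpa)
    min_lag = max(smooth_w, 2)
    max_lag = max(int(round(slope_window_s * fs)), min_lag + 1)
    half = smooth_w // 2
    # the trough index can sit anywhere in a flat slip bottom (noise), so
    # look back far enough to reach the pre-slip level, then take the
    # deepest point after it
    back = int(round(4.0 * fs))
    raw: list[_Candidate] = []
    for trough in troughs:
        lo = max(trough - back, 0)
        hi = min(trough + half, n - 1)
        i_max = lo + int(np.argmax(s[lo:trough + 1]))
        i_min = i_max + 1 + int(np.argmin(r[i_max + 1:hi + 1])) if i_max < hi else hi
        if i_min <= i_max:
            continue
        magnitude = float(r[i_max] - r[i_min])
        # a genuine slip descends below the running baseline; a positive
        # residual decaying back to zero (baseline catch-up after a long
        # slip) must not count
        if r[i_min] > -0.5 * magnitude:
            continue
        rate = _max_descent_rate(s[i_max:i_min + half + 1], dt, min_lag, max_lag)
        raw.append(_Candidate(i_start=i_max, i_end=i_min, magnitude=magnitude,
                              rate=rate))
    raw.sort(key=lambda c: c.i_start)
    merged: list[_Candidate] = []
    gap = merge_gap_s * fs
    for c in raw:
        if merged and c.i_start - merged[-1].i_end < gap:
            m = merged[-1]
            m.i_end = max(m.i_end, c.i_end)
            m.magnitude = max(m.magnitude, c.magnitude)
            m.rate = max(m.rate, c.rate)
        else:
            merged.append(c)
    return merged


def _phase_of(start_s: float, total_s: float) -> str:
    frac = start_s / total_s if total_s > 0 else 0.0
    if frac < 0.25:
        return PHASE_BEGIN
    if frac < 0.85:
        return PHASE_MID
    return PHASE_END


def detect_irregular_fluctuations(
    trace: VacuumTrace,
    rule: FluctuationRule,
    *,
    baseline_window_s: float = 5.0,
    smooth_s: float = 0.025,
    slope_window_s: float = 0.25,
    merge_gap_s: float = 0.5,
    candidate_prominence_kpa: float = 8.0,
) -> list[SlipEvent]:
    """Detect irregular vacuum fluctuations satisfying ``rule``.

    The SMT vacuum is detrended with a centred moving-median baseline
    (window ``baseline_window_s``); candidate descents are local-maximum to
    local-minimum excursions of the residual found by trough prominence.
    An event is returned when the residual magnitude (local max minus local
    min) is at least ``rule.magnitude_kpa`` *and* the steepest descent of
    the lightly smoothed residual over windows of ``smooth_s`` to
    ``slope_window_s`` is at least ``rule.drop_rate_kpa_s``.  Candidates
    closer than ``merge_gap_s`` merge into one event before thresholding.

    Returned events are sorted, non-overlapping, and each satisfies both
    thresholds as measured.
    """
    if len(trace.time_s) == 0:
        return []
    t = trace.time_s
    total = t[-1] + (t[1] - t[0] if len(t) > 1 else 0.0)
    prominence = min(candidate_prominence_kpa, 0.6 * rule.magnitude_kpa)
    clusters = _candidate_events(
        trace,
        baseline_window_s=baseline_window_s,
        smooth_s=smooth_s,
        slope_window_s=slope_window_s,
        merge_gap_s=merge_gap_s,
        candidate_prominence_kpa=prominence,
    )
    events = []
    for c in clusters:
        if c.magnitude < rule.magnitude_kpa - 1e-9:
            continue
        if c.rate < rule.drop_rate_kpa_s - 1e-9:
            continue
        start = float(t[c.i_start])
        span = float(t[c.i_end] - t[c.i_start])
        duration = max(span, c.magnitude / c.rate)
        events.append(
            SlipEvent(
                start_s=start,
                duration_s=duration,
                magnitude_kpa=c.magnitude,
                max_drop_rate_kpa_s=c.rate,
                phase_label=_phase_of(start, total),
            )
        )
    return events


def classify_slp_v(events: Sequence[SlipEvent]) -> int:
    """Vacuum-based slip flag: present iff one or more events."""
    return int(len(events) >= 1)


def detect_observer(
    events: Sequence[SlipEvent],
    window: ObserverWindow,
    unit_on_s: float,
    miss_prob: float,
    seed: int,
    observation_index: int = 0,
) -> int:
    """Stochastic audible detection: present iff at least one ground-truth
    event overlapping the observer's window is heard.

    Each overlapping event is heard independently with probability
    ``1 - miss_prob``; events of any duration qualify.  The random stream
    is keyed on ``(seed, observer_id, observation_index)``.
    """
    if not 0.0 <= miss_prob <= 1.0:
        raise ValueError("miss_prob must lie in [0, 1]")
    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(window.observer_id, observation_index))
    )
    return observer_hears(events, window.start_frac, window.end_frac,
                          unit_on_s, miss_prob, rng)


# ---------------------------------------------------------------------------
# Phase segmentation and cyclic-vacuum summary


def segment_phases(
    trace: VacuumTrace,
    *,
    attach_threshold_kpa: float = 20.0,
    plateau_tolerance_kpa: float = 0.8,
    plateau_slope_kpa_s: float = 0.025,
    smooth_window_s: float = 15.0,
    overmilking_margin_kpa: float = OVERMILKING_MARGIN_KPA,
    overmilking_min_s: float = 10.0,
    takeoff_threshold_kpa: float = 30.0,
) -> MilkingPhases:
    """Rule-based milking-phase boundaries from the vacuum trace alone.

    The vacuum is first averaged over one second (cancels the duty-cycled
    pulsation component) and then smoothed with a centred
    ``smooth_window_s`` moving median (robust against slip transients).
    Rules:

    * start of milking: first sample above ``attach_threshold_kpa``;
    * start of take-off: last sample above ``takeoff_threshold_kpa`` (the
      terminal vacuum decay);
    * start of peak flow: first time the smoothed vacuum is both within
      ``plateau_tolerance_kpa`` of its session minimum (vacuum depression
      is deepest at peak milk flow) and locally flat (centred slope above
      ``-plateau_slope_kpa_s``); the attach transient and take-off decay
      are excluded from the minimum search;
    * start of cyclic fluctuations: identified with the peak-flow start
      (pulsation-locked fluctuation is fully developed once flow peaks);
    * start of overmilking: last crossing of the smoothed vacuum above
      (end-of-session vacuum level - ``overmilking_margin_kpa``) — the
      vacuum rebound as gland flow dies away — kept only when at least
      ``overmilking_min_s`` of overmilking precede take-off;
    * end of milking: trace end.

    Boundaries degenerate (clamp toward the trace end) on traces too short
    for the rules, with a warning.
    """
    t = trace.time_s
    n = len(t)
    if n == 0:
        raise ValueError("empty trace")
    v = trace.smt_vacuum_kpa
    fs = trace.sampling_rate_hz if n >= 2 else 1.0
    end = float(n / fs)

    above = np.nonzero(v > attach_threshold_kpa)[0]
    start = float(t[above[0]]) if above.size else 0.0

    above_off = np.nonzero(v > takeoff_threshold_kpa)[0]
    takeoff_idx = int(above_off[-1]) if above_off.size else n - 1
    takeoff = float(t[takeoff_idx])

    m1 = _movmean(v, _odd(max(int(round(1.0 * fs)), 3)))
    m = _rolling_median(m1, _odd(max(int(round(smooth_window_s * fs)), 3)))
    i0 = int(round((start + 5.0) * fs))
    ref_idx = takeoff_idx - int(round((OVERMILKING_REF_OFFSET_S - 2.0) * fs))
    if i0 >= ref_idx or ref_idx <= 0:
        logger.warning("trace %s too short for phase rules; clamping",
                       trace.observation_id)
        return MilkingPhases(start, end, end, end, end, end)

    interior = m[i0:ref_idx]
    # robust session minimum: a long slip transient can undercut the
    # plateau level, so use a low percentile rather than the minimum
    vmin = float(np.percentile(interior, 10.0))
    # slope from a short slip-light filter: the long median advances the
    # ramp-to-plateau corner by up to half its window
    ms = _rolling_median(m1, _odd(max(int(round(3.0 * fs)), 3)))
    w = int(round(2.5 * fs))
    slope = np.full(n, np.inf)
    if n > 2 * w:
        slope[w:n - w] = (ms[2 * w:] - ms[:n - 2 * w]) / (2 * w / fs)
    near_min = interior <= vmin + plateau_tolerance_kpa
    flat = slope[i0:ref_idx] >= -plateau_slope_kpa_s
    hit = np.nonzero(near_min & flat)[0]
    peak_idx = i0 + (int(hit[0]) if hit.size else int(np.argmax(near_min)))
    peak_start = float(t[peak_idx])

    # end-of-session vacuum level ~6 s before the end of milking, taken
    # from the pulsation-free mean in a short interior window (the long
    # median is right-truncated there)
    w15 = int(round(1.5 * fs))
    end_level = float(np.median(m1[max(0, ref_idx - w15):ref_idx + w15]))
    threshold = end_level - overmilking_margin_kpa
    below = np.nonzero(m[peak_idx:ref_idx] < threshold)[0]
    over_idx = peak_idx + int(below[-1]) + 1 if below.size else takeoff_idx
    over_start = float(t[min(over_idx, takeoff_idx)])
    if takeoff - over_start < overmilking_min_s:
        over_start = takeoff

    vals = sorted([start, peak_start, over_start, takeoff, end])
    if [start, peak_start, over_start, takeoff, end] != vals:
        logger.warning("trace %s: phase rules out of order; clamping",
                       trace.observation_id)
        start, peak_start, over_start, takeoff, end = vals
    return MilkingPhases(
        start_of_milking_s=start,
        peak_flow_start_s=peak_start,
        cyclic_fluct_start_s=peak_start,
        overmilking_start_s=over_start,
        takeoff_start_s=takeoff,
        end_of_milking_s=end,
    )


def avg_cyclic_vacuum(trace: VacuumTrace, phases: MilkingPhases,
                      pulsation_rate_cpm: float = 60.0) -> float:
    """Average SMT vacuum over ten pulsation cycles starting 60 s after the
    start of the peak-flow period: the mean of the ten per-cycle means."""
    fs = trace.sampling_rate_hz
    cycle_s = 60.0 / pulsation_rate_cpm
    start_s = phases.peak_flow_start_s + 60.0
    needed = start_s + 10.0 * cycle_s
    available = len(trace.time_s) / fs
    if needed > available + 1e-9:
        raise ValueError(
            f"trace too short for cyclic-vacuum average: needs {needed:.2f} s, "
            f"has {available:.2f} s"
        )
    cycle_means = []
    for k in range(10):
        i0 = int(round((start_s + k * cycle_s) * fs))
        i1 = int(round((start_s + (k + 1) * cycle_s) * fs))
        cycle_means.append(float(trace.smt_vacuum_kpa[i0:i1].mean()))
    return float(np.mean(cycle_means))
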