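"""Synthetic milking-vacuum signal generator.

Generates per-observation short-milk-tube (SMT) vacuum traces sampled at
200 Hz with a 60 cycles/min pulsation-locked cyclic component, a
milk-flow-dependent vacuum depression, injected liner-slip transients
(rapid vacuum drops with controlled magnitude and descent rate), a 0-255
air-bleed channel that rises during slips, and observation-level milking
characteristics (milk yield, unit-on time, flow rates) with realistic
herd-level means and spreads.

The generator provides the ground truth against which the rule-based slip
detectors are evaluated: every injected :class:`SlipEvent` is returned
alongside the trace, and all randomness is driven by per-observation seed
streams so a herd can be regenerated bit-identically.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "SimulationConfig",
    "VacuumTrace",
    "SlipEvent",
    "MilkingPhases",
    "MilkingObservation",
    "HerdData",
    "simulate_observation",
    "simulate_herd",
    "simulate_raters",
    "implied_cell_probs",
]

# Phase labels used for ground-truth slip events and observer stations.
PHASE_BEGIN = "begin"
PHASE_MID = "mid"
PHASE_END = "end"

# Overmilking boundary rule shared by the simulator's ground truth and the
# trace-based detector: overmilking starts at the last time the slow
# (flow-driven) vacuum sits more than OVERMILKING_MARGIN_KPA below its
# end-of-session level, referenced OVERMILKING_REF_OFFSET_S before the end.
# With the default machine settings this corresponds to gland flow falling
# to roughly the cluster-remover threshold.
OVERMILKING_MARGIN_KPA = 2.5
OVERMILKING_REF_OFFSET_S = 6.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic milking-observation generator.

    Defaults encode the milking-system settings of the study herds (200 Hz
    sampling, 60 cycles/min pulsation at a 65:35 ratio, flow-responsive
    system vacuum of 42/46 kPa switching at 2.3 kg/min) and the reported
    herd-level milking characteristics (milk yield 15.9 +/- 4.2 kg,
    unit-on time 255 +/- 56 s).  Slip rates are Poisson means of injected
    events per observation and phase; their defaults match the observed
    phase-wise slip frequencies of 5.8 % / 4.8 % / 2.8 % (rare-event
    regime, where the Poisson mean and the presence probability nearly
    coincide).
    """

    sampling_rate_hz: float = 200.0
    pulsation_rate_cpm: float = 60.0
    pulsation_ratio: float = 0.65
    system_vacuum_low_kpa: float = 42.0
    system_vacuum_high_kpa: float = 46.0
    flow_switch_kg_min: float = 2.3
    milk_yield_mean_kg: float = 15.9
    milk_yield_sd_kg: float = 4.2
    unit_on_mean_s: float = 255.0
    unit_on_sd_s: float = 56.0
    slip_rate_begin: float = 0.058
    slip_rate_mid: float = 0.048
    slip_rate_end: float = 0.028
    slip_magnitude_range_kpa: tuple[float, float] = (14.0, 35.0)
    slip_rate_range_kpa_s: tuple[float, float] = (56.0, 200.0)
    slip_duration_lognormal: tuple[float, float] = (0.7, 1.0)
    bimodality_prob: float = 0.3
    observer_miss_prob: float = 0.0
    airbleed_gain: float = 7.0
    noise_sd_kpa: float = 0.5
    seed: int = 0
    # secondary shape parameters (not varied in the study conditions)
    cyclic_amplitude_kpa: float = 3.0
    airbleed_baseline: float = 40.0
    airbleed_noise_sd: float = 10.0
    flow_depression_kpa_per_kg_min: float = 2.5
    # response width chosen so vacuum is strictly monotone in milk flow
    vacuum_switch_width_kg_min: float = 0.5
    recovery_tau_s: float = 0.3
    phase_begin_frac: float = 0.25
    phase_end_frac: float = 0.15
    ramp_duration_s: float = 30.0
    decline_start_frac: float = 0.6
    end_flow_kg_min: float = 0.3
    attach_transient_s: float = 2.0

    def __post_init__(self) -> None:
        errs = []
        for name in ("pulsation_ratio", "bimodality_prob", "observer_miss_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errs.append(f"{name}={v} must be in [0, 1]")
        for name in (
            "slip_rate_begin",
            "slip_rate_mid",
            "slip_rate_end",
            "milk_yield_sd_kg",
            "unit_on_sd_s",
            "noise_sd_kpa",
            "airbleed_gain",
            "airbleed_noise_sd",
            "cyclic_amplitude_kpa",
        ):
            v = getattr(self, name)
            if v < 0:
                errs.append(f"{name}={v} must be >= 0")
        for name in ("sampling_rate_hz", "milk_yield_mean_kg", "unit_on_mean_s",
                     "recovery_tau_s"):
            v = getattr(self, name)
            if v <= 0:
                errs.append(f"{name}={v} must be > 0")
        lo, hi = self.slip_magnitude_range_kpa
        if not (0 < lo <= hi):
            errs.append(f"slip_magnitude_range_kpa={self.slip_magnitude_range_kpa} invalid")
        lo, hi = self.slip_rate_range_kpa_s
        if not (0 < lo <= hi):
            errs.append(f"slip_rate_range_kpa_s={self.slip_rate_range_kpa_s} invalid")
        if not 0.0 < self.phase_begin_frac < 1.0 or not 0.0 < self.phase_end_frac < 1.0 \
                or self.phase_begin_frac + self.phase_end_frac >= 1.0:
            errs.append("phase fractions must partition (0, 1)")
        # Nyquist for the pulsation-locked cyclic component
        if self.sampling_rate_hz <= 2.0 * self.pulsation_rate_cpm / 60.0:
            errs.append(
                f"sampling_rate_hz={self.sampling_rate_hz} must exceed twice the "
                f"pulsation frequency {self.pulsation_rate_cpm / 60.0} Hz"
            )
        if errs:
            raise ValueError("invalid SimulationConfig: " + "; ".join(errs))

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown SimulationConfig keys: {unknown}")
        d = dict(d)
        for k in ("slip_magnitude_range_kpa", "slip_rate_range_kpa_s",
                  "slip_duration_lognormal"):
            if k in d and d[k] is not None:
                d[k] = tuple(float(x) for x in d[k])
        return cls(**d)


@dataclass(frozen=True)
class SlipEvent:
    """A liner-slip transient: a rapid vacuum drop and its recovery.

    ``max_drop_rate_kpa_s`` is always at least ``magnitude_kpa /
    duration_s`` (a drop of the full magnitude must fit into the event).
    """

    start_s: float
    duration_s: float
    magnitude_kpa: float
    max_drop_rate_kpa_s: float
    phase_label: str

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise ValueError(f"start_s={self.start_s} must be >= 0")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s={self.duration_s} must be > 0")
        if self.magnitude_kpa <= 0 or self.max_drop_rate_kpa_s <= 0:
            raise ValueError("magnitude_kpa and max_drop_rate_kpa_s must be > 0")
        if self.max_drop_rate_kpa_s < self.magnitude_kpa / self.duration_s - 1e-9:
            raise ValueError(
                "max_drop_rate_kpa_s must be >= magnitude_kpa / duration_s"
            )
        if self.phase_label not in (PHASE_BEGIN, PHASE_MID, PHASE_END):
            raise ValueError(f"phase_label={self.phase_label!r} invalid")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class MilkingPhases:
    """Ordered phase boundaries of one milking observation, in seconds."""

    start_of_milking_s: float
    peak_flow_start_s: float
    cyclic_fluct_start_s: float
    overmilking_start_s: float
    takeoff_start_s: float
    end_of_milking_s: float

    def __post_init__(self) -> None:
        vals = [
            self.start_of_milking_s,
            self.peak_flow_start_s,
            self.cyclic_fluct_start_s,
            self.overmilking_start_s,
            self.takeoff_start_s,
            self.end_of_milking_s,
        ]
        if any(b < a - 1e-9 for a, b in zip(vals, vals[1:])):
            raise ValueError(f"phase boundaries must be non-decreasing: {vals}")


@dataclass
class VacuumTrace:
    """Sampled SMT vacuum and air-bleed channels for one observation."""

    time_s: np.ndarray
    smt_vacuum_kpa: np.ndarray
    airbleed_index: np.ndarray
    observation_id: str
    truth_phases: Optional[MilkingPhases] = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.smt_vacuum_kpa = np.asarray(self.smt_vacuum_kpa, dtype=float)
        self.airbleed_index = np.asarray(self.airbleed_index, dtype=float)
        n = len(self.time_s)
        if len(self.smt_vacuum_kpa) != n or len(self.airbleed_index) != n:
            raise ValueError("all channels must have equal length")
        if n >= 2:
            steps = np.diff(self.time_s)
            if steps.min() <= 0 or not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
                raise ValueError("time_s must increase with a constant step")
        if n and (self.smt_vacuum_kpa.min() < 0 or self.smt_vacuum_kpa.max() > 60):
            raise ValueError("smt_vacuum_kpa must lie in [0, 60]")
        if n and (self.airbleed_index.min() < 0 or self.airbleed_index.max() > 255):
            raise ValueError("airbleed_index must lie in [0, 255]")

    @property
    def sampling_rate_hz(self) -> float:
        if len(self.time_s) < 2:
            raise ValueError("trace too short to infer sampling rate")
        return 1.0 / (self.time_s[1] - self.time_s[0])

    @property
    def duration_s(self) -> float:
        return len(self.time_s) / self.sampling_rate_hz

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "smt_vacuum_kpa": self.smt_vacuum_kpa,
                "airbleed_index": self.airbleed_index,
            }
        )


# Flag columns of a MilkingObservation; None means "method not applied".
FLAG_COLUMNS = ("slp_mm", "slp_ob1", "slp_ob2", "slp_ob3", "slp_any", "slp_v1", "slp_v2")


@dataclass
class MilkingObservation:
    """One cow-milking record with milking characteristics and slip flags."""

    observation_id: str
    cow_id: str
    lactation_number: int
    dim: int
    milk_yield_kg: float
    two_min_yield_kg: float
    unit_on_s: float
    avg_flow_kg_min: float
    slp_mm: Optional[int] = None
    slp_ob1: Optional[int] = None
    slp_ob2: Optional[int] = None
    slp_ob3: Optional[int] = None
    slp_any: Optional[int] = None
    slp_v1: Optional[int] = None
    slp_v2: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lactation_number < 1:
            raise ValueError("lactation_number must be >= 1")
        if self.dim < 0:
            raise ValueError("dim must be >= 0")
        if self.unit_on_s <= 0:
            raise ValueError("unit_on_s must be > 0")
        expected = self.milk_yield_kg / (self.unit_on_s / 60.0)
        if abs(self.avg_flow_kg_min - expected) > 1e-6:
            raise ValueError(
                f"avg_flow_kg_min={self.avg_flow_kg_min} != milk_yield/(unit_on/60)="
                f"{expected}"
            )
        for name in FLAG_COLUMNS:
            v = getattr(self, name)
            if v is not None and v not in (0, 1):
                raise ValueError(f"{name}={v!r} must be 0, 1 or None")


@dataclass
class HerdData:
    """A simulated herd: observation table, ground-truth events, optional traces."""

    observations: pd.DataFrame
    events: pd.DataFrame
    traces: Optional[list] = None


def _obs_seedseq(config: SimulationConfig, observation_index: int, stream: int):
    """Deterministic, parallel-safe seed stream per observation and purpose."""
    return np.random.SeedSequence(config.seed, spawn_key=(observation_index, stream))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float = 0.0) -> float:
    """Draw from N(mean, sd) truncated to (low, inf) by resampling."""
    if sd == 0:
        return max(mean, np.nextafter(low, np.inf))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > low:
            return float(v)
    raise RuntimeError("truncated normal resampling did not converge")


def _phase_windows(config: SimulationConfig, unit_on_s: float) -> dict[str, tuple[float, float]]:
    b = config.phase_begin_frac * unit_on_s
    e = (1.0 - config.phase_end_frac) * unit_on_s
    return {PHASE_BEGIN: (0.0, b), PHASE_MID: (b, e), PHASE_END: (e, unit_on_s)}


@dataclass
class _ObservationDraw:
    """All random quantities of one observation except sample-level noise."""

    observation_id: str
    cow_id: str
    lactation_number: int
    dim: int
    unit_on_s: float
    milk_yield_kg: float
    bimodal: bool
    events: list


def _draw_observation(config: SimulationConfig, observation_index: int) -> _ObservationDraw:
    rng = np.random.default_rng(_obs_seedseq(config, observation_index, 0))
    unit_on = _truncated_normal(rng, config.unit_on_mean_s, config.unit_on_sd_s,
                                low=30.0)
    milk_yield = _truncated_normal(rng, config.milk_yield_mean_kg,
                                   config.milk_yield_sd_kg, low=0.5)
    lact = int(rng.choice([1, 2, 3], p=[0.33, 0.19, 0.48]))
    if lact == 3:
        lact += int(rng.integers(0, 4))
    dim = int(round(_truncated_normal(rng, 143.0, 109.0, low=1.0)))
    bimodal = bool(rng.random() < config.bimodality_prob)

    rates = {
        PHASE_BEGIN: config.slip_rate_begin,
        PHASE_MID: config.slip_rate_mid,
        PHASE_END: config.slip_rate_end,
    }
    windows = _phase_windows(config, unit_on)
    mu, sigma = config.slip_duration_lognormal
    mag_lo, mag_hi = config.slip_magnitude_range_kpa
    rate_lo, rate_hi = config.slip_rate_range_kpa_s
    min_dur = 3.0 / config.sampling_rate_hz
    events = []
    # slips happen while the unit is milking: not during the attachment
    # transient nor once take-off has begun
    lo_bound = config.attach_transient_s + 1.0
    hi_bound = unit_on - 4.0
    for phase in (PHASE_BEGIN, PHASE_MID, PHASE_END):
        count = int(rng.poisson(rates[phase]))
        w0, w1 = max(windows[phase][0], lo_bound), min(windows[phase][1], hi_bound)
        if w1 <= w0:
            continue
        for _ in range(count):
            start = float(rng.uniform(w0, w1))
            duration = float(np.exp(rng.normal(mu, sigma)))
            duration = float(np.clip(duration, min_dur, max(unit_on - start - 0.05,
                                                            min_dur)))
            magnitude = float(rng.uniform(mag_lo, mag_hi))
            drop_rate = float(rng.uniform(rate_lo, rate_hi))
            drop_rate = max(drop_rate, magnitude / duration)
            events.append(
                SlipEvent(
                    start_s=start,
                    duration_s=duration,
                    magnitude_kpa=magnitude,
                    max_drop_rate_kpa_s=drop_rate,
                    phase_label=phase,
                )
            )
    events.sort(key=lambda e: e.start_s)
    return _ObservationDraw(
        observation_id=f"obs{observation_index:05d}",
        cow_id=f"cow{observation_index:05d}",
        lactation_number=lact,
        dim=dim,
        unit_on_s=unit_on,
        milk_yield_kg=milk_yield,
        bimodal=bimodal,
        events=events,
    )


def _flow_curve(config: SimulationConfig, draw: _ObservationDraw,
                t: np.ndarray) -> tuple[np.ndarray, MilkingPhases]:
    """Trapezoidal milk-flow curve (kg/min) scaled to the drawn milk yield.

    Ramp to peak flow, plateau, linear decline to a residual end flow,
    2 s take-off at the very end.  An optional bimodal dip (cisternal milk
    exhausted before alveolar let-down) interrupts the ramp.
    """
    unit_on = draw.unit_on_s
    t_ramp = min(config.ramp_duration_s, 0.4 * unit_on)
    t_dec = max(config.decline_start_frac * unit_on, t_ramp + 1.0)
    t_off = max(unit_on - 4.0, t_dec + 1.0)
    shape = np.interp(t, [0.0, t_ramp, t_dec, t_off, unit_on],
                      [0.0, 1.0, 1.0, 0.08, 0.0])
    plateau_start = t_ramp
    if draw.bimodal:
        # cosine dip to ~30 % of the ramp flow between 0.5 and 1.5 ramp times
        d0, d1 = 0.5 * t_ramp, min(1.5 * t_ramp, t_dec)
        in_dip = (t >= d0) & (t < d1)
        dip = np.zeros_like(t)
        dip[in_dip] = 0.7 * 0.5 * (1 - np.cos(2 * np.pi * (t[in_dip] - d0) / (d1 - d0)))
        shape = shape * (1.0 - dip)
        plateau_start = d1  # sustained peak flow only begins after the dip
    integral_min = float(np.trapezoid(shape, t) / 60.0)  # kg per unit shape
    peak = draw.milk_yield_kg / integral_min if integral_min > 0 else 0.0
    flow = peak * shape
    # ground-truth overmilking boundary: same vacuum-rebound rule the
    # detector applies, evaluated on the clean flow-driven vacuum curve
    takeoff = unit_on - 2.0
    v_clean = _clean_vacuum(config, flow)
    ref_idx = min(int(np.searchsorted(t, unit_on - OVERMILKING_REF_OFFSET_S)),
                  len(t) - 1)
    threshold = float(v_clean[ref_idx]) - OVERMILKING_MARGIN_KPA
    peak_idx = int(np.searchsorted(t, plateau_start))
    below = np.nonzero(v_clean[peak_idx:ref_idx] < threshold)[0]
    over = float(t[peak_idx + below[-1] + 1]) if below.size else takeoff
    if takeoff - over < 10.0:
        over = takeoff
    phases = MilkingPhases(
        start_of_milking_s=0.0,
        peak_flow_start_s=float(plateau_start),
        cyclic_fluct_start_s=float(plateau_start),
        overmilking_start_s=min(over, takeoff),
        takeoff_start_s=takeoff,
        end_of_milking_s=unit_on,
    )
    return flow, phases


def _slip_depression(t: np.ndarray, events: Sequence[SlipEvent],
                     tau: float) -> np.ndarray:
    """Summed vacuum depression of all slip events at sample times t."""
    dep = np.zeros_like(t)
    for ev in events:
        t_d = ev.magnitude_kpa / ev.max_drop_rate_kpa_s
        rel = t - ev.start_s
        shape = np.zeros_like(t)
        descending = (rel >= 0) & (rel < t_d)
        shape[descending] = rel[descending] / t_d
        holding = (rel >= t_d) & (rel < ev.duration_s)
        shape[holding] = 1.0
        recovering = rel >= ev.duration_s
        shape[recovering] = np.exp(-(rel[recovering] - ev.duration_s) / tau)
        dep += ev.magnitude_kpa * shape
    return dep


def _clean_vacuum(config: SimulationConfig, flow: np.ndarray) -> np.ndarray:
    """Noise-free flow-driven SMT vacuum: flow-responsive system vacuum
    minus a flow-proportional depression."""
    sys_vac = config.system_vacuum_low_kpa + (
        config.system_vacuum_high_kpa - config.system_vacuum_low_kpa
    ) * expit((flow - config.flow_switch_kg_min) / config.vacuum_switch_width_kg_min)
    return sys_vac - config.flow_depression_kpa_per_kg_min * flow


def _synthesize_trace(config: SimulationConfig, draw: _ObservationDraw
                      ) -> tuple[VacuumTrace, np.ndarray, MilkingPhases]:
    """Build the sampled vacuum and air-bleed channels for one draw."""
    fs = config.sampling_rate_hz
    n = max(int(round(draw.unit_on_s * fs)), 2)
    t = np.arange(n) / fs
    rng = np.random.default_rng(_obs_seedseq(config, int(draw.observation_id[3:]), 1))

    flow, phases = _flow_curve(config, draw, t)
    v = _clean_vacuum(config, flow)

    # pulsation-locked cyclic component, amplitude scaled with flow
    phase = np.mod(t * config.pulsation_rate_cpm / 60.0, 1.0)
    square = np.where(phase < config.pulsation_ratio, 1.0, -1.0)
    k = max(int(round(0.015 * fs)), 1)
    square = np.convolve(square, np.ones(k) / k, mode="same")
    square -= 2.0 * config.pulsation_ratio - 1.0
    peak_flow = max(flow.max(), 1e-9)
    cyclic = config.cyclic_amplitude_kpa * np.clip(flow / peak_flow, 0.0, 1.0) * square
    v = v + cyclic

    v -= _slip_depression(t, draw.events, config.recovery_tau_s)

    # attachment transient and take-off decay
    v *= np.clip(t / config.attach_transient_s, 0.0, 1.0)
    tail = t > draw.unit_on_s - 2.0
    v[tail] *= np.clip((draw.unit_on_s - t[tail]) / 2.0, 0.05, 1.0)

    v += rng.normal(0.0, config.noise_sd_kpa, size=n)
    v = np.clip(v, 0.0, 60.0)

    ab = config.airbleed_baseline + rng.normal(0.0, config.airbleed_noise_sd, size=n)
    for ev in draw.events:
        mask = (t >= ev.start_s) & (t < ev.end_s)
        ab[mask] += config.airbleed_gain * ev.magnitude_kpa
    ab = np.clip(ab, 0.0, 255.0)

    trace = VacuumTrace(
        time_s=t,
        smt_vacuum_kpa=v,
        airbleed_index=ab,
        observation_id=draw.observation_id,
        truth_phases=phases,
    )
    return trace, flow, phases


def _make_observation(config: SimulationConfig, draw: _ObservationDraw,
                      flow: Optional[np.ndarray], t: Optional[np.ndarray]
                      ) -> MilkingObservation:
    if flow is not None and t is not None:
        first2 = t <= 120.0
        two_min = float(np.trapezoid(flow[first2], t[first2]) / 60.0)
    else:
        # analytic integral of the trapezoid over the first two minutes is
        # not needed when no trace is materialized; approximate from shape
        two_min = min(draw.milk_yield_kg, draw.milk_yield_kg * 120.0 / draw.unit_on_s * 1.4)
    return MilkingObservation(
        observation_id=draw.observation_id,
        cow_id=draw.cow_id,
        lactation_number=draw.lactation_number,
        dim=draw.dim,
        milk_yield_kg=round(draw.milk_yield_kg, 6),
        two_min_yield_kg=round(two_min, 6),
        unit_on_s=round(draw.unit_on_s, 6),
        avg_flow_kg_min=round(draw.milk_yield_kg, 6) / (round(draw.unit_on_s, 6) / 60.0),
    )


def simulate_observation(config: SimulationConfig, observation_index: int
                         ) -> tuple[VacuumTrace, list[SlipEvent], MilkingObservation]:
    """Simulate one milking observation.

    Returns the sampled vacuum/air-bleed trace, the ground-truth slip
    events sorted by start time, and the observation record.  Output is a
    deterministic function of ``(config.seed, observation_index)``.
    """
    if observation_index < 0:
        raise ValueError("observation_index must be >= 0")
    draw = _draw_observation(config, observation_index)
    trace, flow, _phases = _synthesize_trace(config, draw)
    obs = _make_observation(config, draw, flow, trace.time_s)
    return trace, list(draw.events), obs


def _events_frame(all_events: list[tuple[str, SlipEvent]]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "observation_id": oid,
                "start_s": ev.start_s,
                "duration_s": ev.duration_s,
                "magnitude_kpa": ev.magnitude_kpa,
                "max_drop_rate_kpa_s": ev.max_drop_rate_kpa_s,
                "phase_label": ev.phase_label,
            }
            for oid, ev in all_events
        ],
        columns=[
            "observation_id",
            "start_s",
            "duration_s",
            "magnitude_kpa",
            "max_drop_rate_kpa_s",
            "phase_label",
        ],
    )


def observer_hears(events: Sequence[SlipEvent], start_frac: float, end_frac: float,
                   unit_on_s: float, miss_prob: float,
                   rng: np.random.Generator) -> int:
    """1 if at least one event overlapping the window is heard."""
    w0, w1 = start_frac * unit_on_s, end_frac * unit_on_s
    for ev in events:
        if ev.start_s < w1 and ev.end_s > w0:
            if rng.random() >= miss_prob:
                return 1
    return 0


def simulate_herd(config: SimulationConfig, n: int,
                  keep_traces: bool = False) -> HerdData:
    """Simulate ``n`` independent milking observations.

    Observation records and ground-truth events are always produced;
    traces are materialized only when ``keep_traces`` is true (they
    dominate memory and run time).  Observer flags ``slp_ob1..3`` and
    ``slp_any`` are filled from the ground-truth events using the
    configured miss probability; detector-based flags (``slp_mm``,
    ``slp_v1``, ``slp_v2``) are left unassessed until detectors run.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    windows = {1: (0.0, config.phase_begin_frac),
               2: (config.phase_begin_frac, 1.0 - config.phase_end_frac),
               3: (1.0 - config.phase_end_frac, 1.0)}
    rows = []
    all_events: list[tuple[str, SlipEvent]] = []
    traces = [] if keep_traces else None
    for i in range(n):
        draw = _draw_observation(config, i)
        if keep_traces:
            trace, flow, _ = _synthesize_trace(config, draw)
            obs = _make_observation(config, draw, flow, trace.time_s)
            traces.append(trace)
        else:
            obs = _make_observation(config, draw, None, None)
        ob_flags = {}
        for k in (1, 2, 3):
            rng_k = np.random.default_rng(_obs_seedseq(config, i, 10 + k))
            w0, w1 = windows[k]
            ob_flags[f"slp_ob{k}"] = observer_hears(
                draw.events, w0, w1, draw.unit_on_s, config.observer_miss_prob, rng_k
            )
        obs.slp_ob1 = ob_flags["slp_ob1"]
        obs.slp_ob2 = ob_flags["slp_ob2"]
        obs.slp_ob3 = ob_flags["slp_ob3"]
        obs.slp_any = int(obs.slp_ob1 or obs.slp_ob2 or obs.slp_ob3)
        rows.append(dataclasses.asdict(obs))
        all_events.extend((obs.observation_id, ev) for ev in draw.events)
    df = pd.DataFrame(rows)
    for col in FLAG_COLUMNS:
        df[col] = df[col].astype("Int64")
    return HerdData(observations=df, events=_events_frame(all_events), traces=traces)


# ---------------------------------------------------------------------------
# Correlated two-rater simulation (test harness for kappa recovery)


def implied_cell_probs(pi1: float, pi2: float, kappa: float
                       ) -> tuple[float, float, float, float]:
    """Cell probabilities (p11, p10, p01, p00) of the unique 2x2 joint
    distribution with margins ``pi1``, ``pi2`` and Cohen's kappa ``kappa``.

    ``p11 = kappa * sqrt(pi1 (1-pi1) pi2 (1-pi2)) + pi1 * pi2``; the other
    cells follow from the margins.  Raises ``ValueError`` naming the first
    violated cell when the combination is infeasible.
    """
    if not (0.0 < pi1 < 1.0 and 0.0 < pi2 < 1.0):
        raise ValueError("pi1 and pi2 must lie strictly in (0, 1)")
    p11 = kappa * math.sqrt(pi1 * (1 - pi1) * pi2 * (1 - pi2)) + pi1 * pi2
    p10 = pi1 - p11
    p01 = pi2 - p11
    p00 = 1.0 - p11 - p10 - p01
    for name, p in (("p11", p11), ("p10", p10), ("p01", p01), ("p00", p00)):
        if p < -1e-12 or p > 1.0 + 1e-12:
            raise ValueError(
                f"infeasible (pi1={pi1}, pi2={pi2}, kappa={kappa}): cell {name}={p:.6f} "
                "outside [0, 1]"
            )
    clip = lambda p: min(max(p, 0.0), 1.0)
    return clip(p11), clip(p10), clip(p01), clip(p00)


def simulate_raters(pi1: float, pi2: float, kappa: float, n: int, seed: int):
    """Sample a 2x2 agreement table of ``n`` paired binary ratings whose
    joint distribution has the given margins and Cohen's kappa."""
    from .agreement import ContingencyTable2x2  # local import, avoids cycle

    if n < 1:
        raise ValueError("n must be >= 1")
    probs = implied_cell_probs(pi1, pi2, kappa)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, probs)
    return ContingencyTable2x2(a=int(counts[0]), b=int(counts[1]),
                               c=int(counts[2]), d=int(counts[3]))


def simulate_raters_many(pi1: float, pi2: float, kappa: float, n: int,
                         n_rep: int, seed: int) -> np.ndarray:
    """Vectorized :func:`simulate_raters`: ``(n_rep, 4)`` counts array."""
    probs = implied_cell_probs(pi1, pi2, kappa)
    rng = np.random.default_rng(seed)
    return rng.multinomial(n, probs, size=n_rep)
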