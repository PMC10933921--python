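"""Tests of the rule-based slip detectors and phase segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linerslip.detect import (
    TYPE1_RULE,
    TYPE2_RULE,
    FluctuationRule,
    MeterRule,
    ObserverWindow,
    avg_cyclic_vacuum,
    classify_slp_v,
    detect_irregular_fluctuations,
    detect_meter_slip,
    detect_observer,
    segment_phases,
)
from linerslip.simulate import SimulationConfig, SlipEvent, simulate_observation

from conftest import make_trace, match_events, ramp_trace


def meter_oracle(airbleed, fs, slip_limit, min_duration_s):
    """Exhaustive run-length scan: any strictly-above run spanning enough samples."""
    run = 0
    best = 0
    for x in airbleed:
        run = run + 1 if x > slip_limit else 0
        best = max(best, run)
    return int(best / fs >= min_duration_s)


class TestMeterSlip:
    def test_constant_just_below_threshold_is_absent(self):
        trace = make_trace(np.full(8000, 45.0), airbleed=np.full(8000, 174.9))
        assert detect_meter_slip(trace, MeterRule(175.0, 30.0)) == 0

    @pytest.mark.parametrize("n_samples,expected", [(5999, 0), (6000, 1)])
    def test_thirty_second_boundary(self, n_samples, expected):
        """A 200 Hz air-bleed run of exactly 30.0 s flips the flag; 29.995 s
        does not (verified against an exhaustive run-length oracle)."""
        n = 10000
        ab = np.full(n, 40.0)
        ab[1000:1000 + n_samples] = 200.0
        trace = make_trace(np.full(n, 45.0), airbleed=ab)
        rule = MeterRule(175.0, 30.0)
        assert detect_meter_slip(trace, rule) == expected
        assert meter_oracle(ab, 200.0, 175.0, 30.0) == expected

    @pytest.mark.parametrize("bump_s,expected", [(45.0, 1), (10.0, 0)])
    def test_bump_duration(self, bump_s, expected):
        n = 12000
        ab = np.full(n, 40.0)
        ab[500:500 + int(bump_s * 200)] = 220.0
        trace = make_trace(np.full(n, 45.0), airbleed=ab)
        assert detect_meter_slip(trace, MeterRule()) == expected
        assert meter_oracle(ab, 200.0, 175.0, 30.0) == expected

    def test_short_trace_is_absent_with_warning(self, caplog):
        trace = make_trace(np.full(100, 45.0), airbleed=np.full(100, 250.0))
        with caplog.at_level("WARNING"):
            assert detect_meter_slip(trace, MeterRule()) == 0
        assert "shorter" in caplog.text

    @settings(max_examples=25, deadline=None)
    @given(
        data=st.data(),
        limit_lo=st.floats(50, 200),
        limit_delta=st.floats(0, 50),
        dur_lo=st.floats(0.5, 20),
        dur_delta=st.floats(0, 20),
    )
    def test_monotone_in_threshold_and_duration(self, data, limit_lo, limit_delta,
                                                dur_lo, dur_delta):
        """Lowering the slip limit or the minimum duration never turns a
        present flag absent."""
        n = 6000
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        ab = rng.uniform(0, 255, size=n)
        # add a coherent bump so present cases actually occur
        j = rng.integers(0, n // 2)
        ab[j:j + rng.integers(100, 4000)] = rng.uniform(150, 255)
        trace = make_trace(np.full(n, 45.0), airbleed=np.clip(ab, 0, 255))
        strict = detect_meter_slip(trace, MeterRule(limit_lo + limit_delta,
                                                    dur_lo + dur_delta))
        loose = detect_meter_slip(trace, MeterRule(limit_lo, dur_lo))
        assert loose >= strict


def fluctuation_presence_oracle(v, fs, rule, max_window_s=0.25):
    """O(n^2) search for a descent satisfying both thresholds on a raw,
    baseline-free trace: some pair i<j drops by >= magnitude, and inside
    [i, j] some sub-window of <= max_window_s descends at >= drop rate."""
    n = len(v)
    dt = 1.0 / fs
    max_lag = int(round(max_window_s * fs))
    steep = np.zeros(n, dtype=bool)
    for i in range(n):
        for lag in range(1, min(max_lag, n - 1 - i) + 1):
            if (v[i] - v[i + lag]) / (lag * dt) >= rule.drop_rate_kpa_s - 1e-9:
                steep[i] = True
                break
    for i in range(n):
        for j in range(i + 1, n):
            if v[i] - v[j] >= rule.magnitude_kpa - 1e-9 and steep[i:j].any():
                return 1
    return 0


class TestIrregularFluctuations:
    def test_constant_trace_has_no_events(self):
        trace = make_trace(np.full(4000, 45.0))
        assert detect_irregular_fluctuations(trace, TYPE1_RULE) == []
        assert detect_irregular_fluctuations(trace, TYPE2_RULE) == []

    def test_empty_trace(self):
        trace = make_trace(np.array([]))
        assert detect_irregular_fluctuations(trace, TYPE1_RULE) == []

    def test_threshold_pairs_on_single_drop(self):
        """A 21 kPa drop in 0.2 s (105 kPa/s) is type 1 and type 2; the same
        drop in 0.3 s (70 kPa/s) is type 2 only."""
        fast = ramp_trace(drop_kpa=21.0, drop_duration_s=0.2)
        slow = ramp_trace(drop_kpa=21.0, drop_duration_s=0.3)
        assert len(detect_irregular_fluctuations(fast, TYPE1_RULE)) == 1
        assert len(detect_irregular_fluctuations(fast, TYPE2_RULE)) == 1
        assert len(detect_irregular_fluctuations(slow, TYPE1_RULE)) == 0
        assert len(detect_irregular_fluctuations(slow, TYPE2_RULE)) == 1

    def test_detected_event_reports_thresholded_measurements(self):
        trace = ramp_trace(drop_kpa=25.0, drop_duration_s=0.2)
        (event,) = detect_irregular_fluctuations(trace, TYPE1_RULE)
        assert event.magnitude_kpa >= 21.0
        assert event.max_drop_rate_kpa_s >= 100.0
        assert event.max_drop_rate_kpa_s >= event.magnitude_kpa / event.duration_s - 1e-9

    @pytest.mark.parametrize("magnitude", [10.0, 14.0, 21.0, 28.0])
    @pytest.mark.parametrize("rate", [40.0, 56.0, 70.0, 100.0, 130.0])
    @pytest.mark.parametrize("rule", [TYPE1_RULE, TYPE2_RULE], ids=["t1", "t2"])
    def test_presence_matches_exhaustive_oracle(self, magnitude, rate, rule):
        """Detection presence equals the O(n^2) max-drop oracle on clean
        single-drop traces across a grid straddling both threshold pairs."""
        trace = ramp_trace(drop_kpa=magnitude, drop_duration_s=magnitude / rate,
                           pre_s=3.0, post_s=3.0)
        got = int(len(detect_irregular_fluctuations(trace, rule)) > 0)
        want = fluctuation_presence_oracle(trace.smt_vacuum_kpa, 200.0, rule)
        assert got == want

    def test_type1_events_subset_of_type2(self, default_config):
        """Threshold dominance: (100, 21) implies (56, 14), so type-2 events
        can never be fewer than type-1 events on the same trace."""
        cfg = default_config.replace(slip_rate_begin=0.6, slip_rate_mid=0.6,
                                     slip_rate_end=0.4)
        for i in range(25):
            trace, _, _ = simulate_observation(cfg, i)
            n1 = len(detect_irregular_fluctuations(trace, TYPE1_RULE))
            n2 = len(detect_irregular_fluctuations(trace, TYPE2_RULE))
            assert n2 >= n1

    def test_high_snr_recovery(self):
        """Injected events far above threshold are recovered nearly
        perfectly (herd-scale version runs in the acceptance suite)."""
        cfg = SimulationConfig(seed=5, slip_rate_begin=0.5, slip_rate_mid=0.4,
                               slip_rate_end=0.3,
                               slip_magnitude_range_kpa=(30.0, 40.0),
                               slip_rate_range_kpa_s=(150.0, 250.0))
        tp = fn = fp = 0
        for i in range(60):
            trace, events, _ = simulate_observation(cfg, i)
            det = detect_irregular_fluctuations(trace, TYPE2_RULE)
            a, b, c = match_events(det, events)
            tp, fn, fp = tp + a, fn + b, fp + c
        assert tp / (tp + fn) >= 0.9
        assert tp / (tp + fp) >= 0.9

    def test_events_sorted_non_overlapping(self, default_config):
        cfg = default_config.replace(slip_rate_mid=3.0)
        trace, _, _ = simulate_observation(cfg, 1)
        events = detect_irregular_fluctuations(trace, TYPE2_RULE)
        for a, b in zip(events, events[1:]):
            assert a.end_s <= b.start_s + 1e-9


class TestClassifySlpV:
    def test_empty_is_absent(self):
        assert classify_slp_v([]) == 0

    @pytest.mark.parametrize("count", [1, 106])
    def test_one_or_more_is_present(self, count):
        ev = SlipEvent(1.0, 0.5, 20.0, 100.0, "mid")
        assert classify_slp_v([ev] * count) == 1


class TestDetectObserver:
    WINDOW = ObserverWindow(2, 0.25, 0.85)

    def test_no_events_in_window_absent(self):
        ev = SlipEvent(10.0, 1.0, 20.0, 100.0, "begin")  # before window
        assert detect_observer([ev], self.WINDOW, 200.0, 0.0, seed=1) == 0

    def test_any_duration_heard_when_miss_prob_zero(self):
        ev = SlipEvent(100.0, 0.1, 20.0, 200.0, "mid")
        assert detect_observer([ev], self.WINDOW, 200.0, 0.0, seed=1) == 1

    def test_certain_miss(self):
        events = [SlipEvent(100.0 + k, 0.5, 20.0, 100.0, "mid") for k in range(10)]
        assert detect_observer(events, self.WINDOW, 200.0, 1.0, seed=1) == 0

    def test_deterministic_stream(self):
        ev = SlipEvent(100.0, 0.5, 20.0, 100.0, "mid")
        flags = {detect_observer([ev], self.WINDOW, 200.0, 0.5, seed=9,
                                 observation_index=4) for _ in range(5)}
        assert len(flags) == 1


class TestSegmentPhases:
    def test_boundaries_recovered_on_simulated_traces(self, default_config):
        """Peak-flow and overmilking onsets land within 5 s of the
        simulator's ground truth for the vast majority of traces."""
        ok_pf = ok_om = n = 0
        for i in range(25):
            trace, _, _ = simulate_observation(default_config, i)
            ph = segment_phases(trace)
            tp = trace.truth_phases
            ok_pf += abs(ph.peak_flow_start_s - tp.peak_flow_start_s) <= 5.0
            ok_om += abs(ph.overmilking_start_s - tp.overmilking_start_s) <= 5.0
            assert abs(ph.takeoff_start_s - tp.takeoff_start_s) <= 5.0
            n += 1
        assert ok_pf / n >= 0.9
        assert ok_om / n >= 0.9

    def test_ordering_invariant(self, default_config):
        trace, _, _ = simulate_observation(default_config, 11)
        ph = segment_phases(trace)
        vals = [ph.start_of_milking_s, ph.peak_flow_start_s, ph.cyclic_fluct_start_s,
                ph.overmilking_start_s, ph.takeoff_start_s, ph.end_of_milking_s]
        assert vals == sorted(vals)

    def test_short_constant_trace_clamps(self, caplog):
        trace = make_trace(np.full(400, 45.0))
        with caplog.at_level("WARNING"):
            ph = segment_phases(trace)
        assert ph.end_of_milking_s == pytest.approx(2.0)
        assert ph.peak_flow_start_s == ph.end_of_milking_s


class TestAvgCyclicVacuum:
    def _phases(self, peak_start):
        from linerslip.simulate import MilkingPhases

        return MilkingPhases(0.0, peak_start, peak_start, 200.0, 250.0, 252.0)

    def test_constant_trace(self):
        trace = make_trace(np.full(200 * 80, 45.0))
        assert avg_cyclic_vacuum(trace, self._phases(0.0)) == pytest.approx(45.0)

    def test_symmetric_square_wave(self):
        fs, cpm = 200.0, 60.0
        n = int(fs * 80)
        t = np.arange(n) / fs
        phase = np.mod(t * cpm / 60.0, 1.0)
        v = 40.0 + np.where(phase < 0.5, 5.0, -5.0)
        trace = make_trace(v, fs=fs)
        assert avg_cyclic_vacuum(trace, self._phases(0.0), cpm) == pytest.approx(40.0)

    def test_matches_brute_force_on_simulated_trace(self, default_config):
        trace, _, _ = simulate_observation(default_config, 0)
        ph = segment_phases(trace)
        got = avg_cyclic_vacuum(trace, ph, default_config.pulsation_rate_cpm)
        # independent re-average straight from the raw samples
        fs = default_config.sampling_rate_hz
        cyc = 60.0 / default_config.pulsation_rate_cpm
        start = ph.peak_flow_start_s + 60.0
        means = [
            trace.smt_vacuum_kpa[
                int(round((start + k * cyc) * fs)):int(round((start + (k + 1) * cyc) * fs))
            ].mean()
            for k in range(10)
        ]
        assert got == pytest.approx(np.mean(means), abs=1e-9)

    def test_insufficient_trace_raises_with_durations(self):
        trace = make_trace(np.full(2000, 45.0))
        with pytest.raises(ValueError, match="needs .* has"):
            avg_cyclic_vacuum(trace, self._phases(0.0))


class TestRuleValidation:
    def test_meter_rule_bounds(self):
        with pytest.raises(ValueError):
            MeterRule(slip_limit=300.0)
        with pytest.raises(ValueError):
            MeterRule(min_duration_s=0.0)

    def test_fluctuation_rule_positive(self):
        with pytest.raises(ValueError):
            FluctuationRule(drop_rate_kpa_s=0.0, magnitude_kpa=10.0, name="x")

    def test_observer_window_ordering(self):
        with pytest.raises(ValueError):
            ObserverWindow(1, 0.5, 0.25)
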