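"""SCR detection and characterization: worked numbers, morphology
measures and detector robustness on simulator ground truth."""

import numpy as np
import pytest

from conftest import make_trace
from edastress.device_model import ConductanceTrace
from edastress.scr_events import (
    DetectionConfig,
    characterize,
    detect_events,
    peak_width,
)
from edastress.synthetic_data import SCRShape, simulate_trace


def censored_recovery_trace():
    """Recording mimicking a stress response with a plateau and an
    interrupted recovery: baseline 4.48 µS, rise to 6.99 µS between 20
    and 42 s, plateau until 94 s, then a slow decline that never reaches
    the 50 % level before the recording ends at 174 s."""
    t = np.arange(0.0, 176.0, 2.0)
    y = np.full(t.shape, 4.48)
    up = (t >= 20) & (t <= 42)
    y[up] = 4.48 + (6.99 - 4.48) * (t[up] - 20) / 22.0
    plateau = (t > 42) & (t <= 94)
    y[plateau] = 6.99
    dn = t > 94
    y[dn] = 6.99 - 0.9 * (t[dn] - 94) / 80.0
    return ConductanceTrace(t, y, source="synthetic")


class TestCharacterize:
    def test_worked_example_amplitude_rise_and_censored_recovery(self):
        tr = censored_recovery_trace()
        ev = characterize(tr, onset_index=10, peak_index=21, recovery_start_time=94.0)
        assert ev.onset_time == 20.0 and ev.peak_time == 42.0
        assert ev.amplitude == pytest.approx(6.99 - 4.48)
        assert ev.amplitude == pytest.approx(2.51)
        assert ev.rise_time == 22.0
        assert ev.recovery_censored
        assert ev.recovery_lower_bound == pytest.approx(174.0 - 94.0)

    def test_censored_lower_bound_defaults_to_peak(self):
        tr = censored_recovery_trace()
        ev = characterize(tr, onset_index=10, peak_index=21)
        assert ev.recovery_censored
        assert ev.recovery_lower_bound == pytest.approx(174.0 - 42.0)

    def test_triangular_bump_half_recovery(self, triangle_trace):
        # 50 % level is crossed halfway down a linear 10 s descent
        ev = characterize(triangle_trace, onset_index=10, peak_index=15)
        assert ev.amplitude == pytest.approx(1.0)
        assert not ev.recovery_censored
        assert ev.recovery_time == pytest.approx(5.0)

    def test_not_an_event(self, triangle_trace):
        with pytest.raises(ValueError, match="not an SCR"):
            characterize(triangle_trace, onset_index=15, peak_index=20)
        with pytest.raises(IndexError):
            characterize(triangle_trace, onset_index=15, peak_index=3)


class TestPeakWidth:
    def test_triangle_width_is_half_the_support(self, triangle_trace):
        ev = characterize(triangle_trace, onset_index=10, peak_index=15)
        assert peak_width(triangle_trace, ev) == pytest.approx(10.0)

    def test_rectangular_pulse_width_is_duration(self):
        vals = np.full(30, 2.0)
        vals[10:15] = 3.0  # 5 samples high at 2 s spacing: d = 10 s
        tr = make_trace(vals)
        ev = characterize(tr, onset_index=9, peak_index=10)
        assert peak_width(tr, ev) == pytest.approx(10.0)

    def test_simulator_bump_width_matches_crossing_search(self):
        shape = SCRShape(stimulus_time=10, latency=3, amplitude=1.5, rise_time=20, recovery_half_time=30)
        sim = simulate_trace([shape], tonic_baseline=4.0, noise_sd=0.0)
        ev = detect_events(sim.trace)[0]
        # brute-force crossing search on a dense version of the shape
        tt = np.arange(0, 120, 0.001)
        dense = 4.0 + shape.evaluate(tt)
        level = ev.onset_value + ev.amplitude / 2
        above = tt[dense >= level]
        assert peak_width(sim.trace, ev) == pytest.approx(above[-1] - above[0], abs=2.0)


class TestDetectEvents:
    def test_flat_trace_has_no_events(self):
        assert detect_events(make_trace(np.full(40, 3.0))) == []

    def test_single_bump_recovered(self):
        shape = SCRShape(stimulus_time=10, latency=3, amplitude=1.0, rise_time=20, recovery_half_time=30)
        sim = simulate_trace([shape], tonic_baseline=2.0, noise_sd=0.02, seed=5)
        events = detect_events(sim.trace)
        assert len(events) == 1
        ev = events[0]
        assert ev.amplitude == pytest.approx(1.0, rel=0.1)
        assert ev.onset_time == pytest.approx(shape.onset_time, abs=2.0)
        assert ev.peak_time == pytest.approx(shape.peak_time, abs=2.0)

    def test_two_bumps_in_time_order(self):
        a = SCRShape(stimulus_time=5, latency=3, amplitude=1.2, rise_time=8, recovery_half_time=10)
        b = SCRShape(stimulus_time=70, latency=3, amplitude=0.8, rise_time=10, recovery_half_time=12)
        sim = simulate_trace([a, b], tonic_baseline=3.0, noise_sd=0.02, duration=160, seed=1)
        events = detect_events(sim.trace)
        assert len(events) == 2
        assert events[0].onset_time < events[1].onset_time
        assert events[0].amplitude == pytest.approx(1.2, rel=0.15)
        assert events[1].amplitude == pytest.approx(0.8, rel=0.15)

    def test_latency_classification(self):
        shape = SCRShape(stimulus_time=20, latency=3, amplitude=1.0, rise_time=10, recovery_half_time=15)
        sim = simulate_trace([shape], tonic_baseline=3.0, noise_sd=0.0)
        ev = detect_events(sim.trace, stimulus_time=20.0)[0]
        assert ev.latency_class == "ER_SCR"
        assert ev.latency == pytest.approx(3.0, abs=2.0)
        # same onset relative to a much earlier stimulus: late, non-specific
        ev_late = detect_events(sim.trace, stimulus_time=2.0)[0]
        assert ev_late.latency_class == "NS_SCR"
        cfg = DetectionConfig(late_latency_class="ER_SCR")
        assert detect_events(sim.trace, cfg=cfg, stimulus_time=2.0)[0].latency_class == "ER_SCR"
        # no stimulus: unknown
        assert detect_events(sim.trace)[0].latency_class == "unknown"

    def test_deterministic_given_input(self):
        shape = SCRShape(stimulus_time=15, latency=2, amplitude=0.7, rise_time=12, recovery_half_time=20)
        sim = simulate_trace([shape], tonic_baseline=5.0, noise_sd=0.02, seed=9)
        assert detect_events(sim.trace) == detect_events(sim.trace)

    def test_unordered_timestamps_rejected(self):
        tr = make_trace(np.full(10, 3.0))
        tr.times = tr.times[::-1].copy()
        with pytest.raises(ValueError, match="increasing"):
            detect_events(tr)

    def test_event_time_ordering_invariant(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            shape = SCRShape.draw(rng, stimulus_time=rng.uniform(5, 50))
            sim = simulate_trace([shape], tonic_baseline=rng.uniform(2, 8), rng=rng)
            for ev in detect_events(sim.trace):
                assert ev.onset_time < ev.peak_time
                assert ev.rise_time > 0 and ev.amplitude > 0
                if not ev.recovery_censored:
                    assert ev.recovery_time > 0

    def test_recovery_slower_than_rise_on_defaults(self):
        """Median recovery exceeds median rise over a seeded batch, the
        expected asymmetry of electrodermal responses."""
        rng = np.random.default_rng(3)
        rises, recs = [], []
        for _ in range(40):
            shape = SCRShape.draw(rng, stimulus_time=rng.uniform(5, 40))
            sim = simulate_trace([shape], tonic_baseline=rng.uniform(2, 8), duration=240, rng=rng)
            for ev in detect_events(sim.trace):
                if not ev.recovery_censored:
                    rises.append(ev.rise_time)
                    recs.append(ev.recovery_time)
        assert len(recs) > 20
        assert np.median(recs) > np.median(rises)
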