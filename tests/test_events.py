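"""Baseline estimation and event detection against planted ground truth."""

import numpy as np
import pytest

import peptidepore as pp


class TestBaseline:
    def test_constant_trace(self):
        tr = pp.Trace(np.zeros(1000), 20000, 100.0)
        assert pp.estimate_baseline(tr) == (0.0, 0.0)

    def test_noisy_baseline_recovered(self):
        tr = pp.simulate_noise_trace(5.0, noise_sd=5.0, seed=3)
        base, sd = pp.estimate_baseline(tr)
        assert abs(base) < 1.0
        assert abs(sd - 5.0) / 5.0 < 0.15

    def test_dominant_level_wins(self):
        x = np.zeros(10000)
        x[9000:] = 110.0  # 10% of the record at the open level
        base, _ = pp.estimate_baseline(pp.Trace(x, 20000, 100.0))
        assert base == pytest.approx(0.0, abs=1e-9)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            pp.estimate_baseline(pp.Trace(np.array([]), 20000, 100.0))


class TestInsertionSteps:
    def test_clean_step_conductance(self):
        tr, _ = pp.simulate_insertion_signal(
            pp.SignalMorphology("step"), 1.1, voltage_mV=100.0, noise_sd=0.0, seed=0
        )
        events = pp.detect_insertion_steps(tr)
        assert len(events) == 1
        assert events[0].conductance_nS == pytest.approx(1.1)
        assert "initial" in events[0].flags

    def test_pure_noise_yields_nothing(self):
        tr = pp.simulate_noise_trace(2.0, noise_sd=5.0, seed=1)
        assert pp.detect_insertion_steps(tr) == []

    def test_planted_staircase_recovered(self):
        tr, gt = pp.simulate_insertion_signal(
            pp.SignalMorphology("step", level_count=5), 1.1, noise_sd=5.0, seed=3
        )
        events = pp.detect_insertion_steps(tr)
        assert len(events) == 5
        for ev, true in zip(events, gt.events):
            assert abs(ev.start_s - true.start_s) < 1e-3  # within 1 ms
            assert ev.amplitude_pA == pytest.approx(110.0, rel=0.1)

    def test_zero_voltage_omits_conductance(self):
        tr, _ = pp.simulate_insertion_signal(
            pp.SignalMorphology("step"), 1.1, noise_sd=0.0, seed=0
        )
        tr.voltage = 0.0
        with pytest.warns(UserWarning, match="conductance"):
            events = pp.detect_insertion_steps(tr)
        assert events[0].conductance_nS is None

    def test_conductance_additivity(self):
        """Two sequential unit insertions: cumulative current 2 g V, and each
        per-step conductance is the unit conductance."""
        tr, _ = pp.simulate_insertion_signal(
            pp.SignalMorphology("step", level_count=2), 1.1, noise_sd=0.0, seed=0
        )
        events = pp.detect_insertion_steps(tr)
        assert tr.current[-1] == pytest.approx(2 * 1.1 * 100.0)
        assert [e.conductance_nS for e in events] == pytest.approx([1.1, 1.1])


class TestBlockades:
    def test_rectangular_dip_exact(self):
        x = np.full(20000, 1050.0)
        x[10000:10036] = 1050.0 - 195.0  # 1.8 ms at 20 kHz
        events = pp.detect_blockade_events(
            pp.Trace(x, 20000, 100.0), 1050.0, threshold_fraction=0.1
        )
        assert len(events) == 1
        assert events[0].duration_ms == pytest.approx(1.8)
        assert events[0].amplitude_pA == pytest.approx(195.0)

    def test_short_excursion_filtered(self):
        x = np.full(20000, 1050.0)
        x[10000:10004] = 800.0  # 0.2 ms < default 0.5 ms dwell
        events = pp.detect_blockade_events(pp.Trace(x, 20000, 100.0), 1050.0)
        assert events == []

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2, 1.5])
    def test_threshold_fraction_validated(self, frac):
        tr = pp.Trace(np.full(100, 1000.0), 20000, 100.0)
        with pytest.raises(ValueError):
            pp.detect_blockade_events(tr, 1000.0, threshold_fraction=frac)

    def test_planted_blockades_recovered(self):
        km = pp.KineticsModel()
        duration = 50 / km.event_rate(100.0, 100.0)
        tr, gt = pp.simulate_event_stream(
            km, 100.0, 100.0, duration, open_current_pA=1050.0, noise_sd=5.0, seed=9
        )
        events = pp.detect_blockade_events(
            tr, 1050.0, threshold_fraction=0.1, noise_sd=5.0
        )
        assert abs(len(events) - len(gt.events)) <= 2

    def test_detection_idempotent_over_segmentation(self):
        """Splitting the trace at a quiet point detects the same events."""
        x = np.full(40000, 1050.0)
        x[5000:5040] = 850.0
        x[30000:30040] = 850.0
        tr = pp.Trace(x, 20000, 100.0)
        whole = pp.detect_blockade_events(tr, 1050.0)
        first = pp.detect_blockade_events(tr.segment(0.0, 1.0), 1050.0)
        second = pp.detect_blockade_events(tr.segment(1.0, 2.0), 1050.0)
        assert len(whole) == len(first) + len(second) == 2
        amps = sorted(e.amplitude_pA for e in whole)
        assert amps == pytest.approx(
            sorted(e.amplitude_pA for e in first + second)
        )
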