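"""Generator contracts: determinism, amplitudes, kinetics laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import peptidepore as pp
from peptidepore.classify import idealize_levels


class TestNoiseTrace:
    def test_zero_noise_is_constant_baseline(self):
        tr = pp.simulate_noise_trace(0.5, noise_sd=0.0, baseline_pA=3.0, seed=0)
        assert np.all(tr.current == 3.0)
        assert len(tr) == 10000

    def test_rms_matches_configured_level(self):
        tr = pp.simulate_noise_trace(10.0, noise_sd=5.0, seed=1)
        rms = tr.current.std()
        assert abs(rms - 5.0) / 5.0 < 0.10

    @pytest.mark.parametrize("dur,rate", [(-1.0, 20000), (1.0, 0), (0.0, 20000)])
    def test_bad_sizing_rejected(self, dur, rate):
        with pytest.raises(ValueError):
            pp.simulate_noise_trace(dur, sampling_rate=rate)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_seeded_determinism(self, seed):
        a = pp.simulate_noise_trace(0.1, noise_sd=4.0, seed=seed)
        b = pp.simulate_noise_trace(0.1, noise_sd=4.0, seed=seed)
        np.testing.assert_array_equal(a.current, b.current)


class TestInsertionSignal:
    def test_clean_step_amplitude_is_g_times_v(self):
        tr, gt = pp.simulate_insertion_signal(
            pp.SignalMorphology("step"), 1.1, voltage_mV=100.0, noise_sd=0.0, seed=0
        )
        assert tr.current[0] == 0.0
        assert tr.current[-1] == pytest.approx(110.0)
        assert gt.events[0].amplitude_pA == pytest.approx(110.0)
        assert gt.label == "step"

    def test_square_top_returns_to_baseline(self):
        tr, _ = pp.simulate_insertion_signal(
            pp.SignalMorphology("square-top"), 1.1, noise_sd=0.0, seed=0
        )
        assert tr.current[-1] == 0.0
        assert tr.current.max() == pytest.approx(110.0)

    def test_multi_level_has_requested_distinct_levels(self):
        tr, _ = pp.simulate_insertion_signal(
            pp.SignalMorphology("multi-level", level_count=3),
            1.1,
            noise_sd=0.0,
            seed=0,
        )
        ideal = idealize_levels(tr, noise_sd=0.0, min_dwell_ms=0.5)
        above = [v for v in ideal.distinct_levels(tol_pA=1.0) if v > 1.0]
        assert len(above) == 3

    def test_unknown_morphology_rejected(self):
        with pytest.raises(ValueError, match="unknown morphology"):
            pp.SignalMorphology("sawtooth")

    def test_ground_truth_lists_every_transition(self):
        _, gt = pp.simulate_insertion_signal(
            pp.SignalMorphology("step", level_count=4), 1.1, noise_sd=3.0, seed=5
        )
        assert len(gt.events) == 4


class TestEventStream:
    def test_zero_concentration_means_zero_events(self):
        km = pp.KineticsModel()
        gt = pp.simulate_event_times(km, 0.0, 100.0, 60.0, seed=0)
        assert len(gt.events) == 0

    def test_rate_linear_in_concentration(self):
        km = pp.KineticsModel()
        n1 = len(pp.simulate_event_times(km, 100.0, 80.0, 300.0, seed=1).events)
        n2 = len(pp.simulate_event_times(km, 200.0, 80.0, 300.0, seed=2).events)
        assert n1 > 100
        ratio = n2 / n1
        assert abs(ratio - 2.0) < 6 * np.sqrt(1 / n1 + 1 / n2) * 2.0

    def test_dwell_peaks_at_vp(self):
        km = pp.KineticsModel()
        voltages = np.arange(40, 201, 20)
        means = [km.mean_dwell(v) for v in voltages]
        assert voltages[int(np.argmax(means))] == km.dwell_peak_voltage

    def test_stream_trace_carries_blockades(self):
        km = pp.KineticsModel()
        tr, gt = pp.simulate_event_stream(
            km, 100.0, 100.0, 10.0, open_current_pA=1050.0, noise_sd=0.0, seed=4
        )
        assert len(gt.events) > 0
        assert tr.current.min() < 1050.0 - 100.0
        assert tr.current.max() == pytest.approx(1050.0)

    def test_rate_log_linear_in_voltage(self):
        km = pp.KineticsModel()
        counts = []
        voltages = [40.0, 60.0, 80.0, 100.0]
        for i, v in enumerate(voltages):
            gt = pp.simulate_event_times(km, 200.0, v, 400.0, seed=10 + i)
            counts.append(len(gt.events))
        slope = np.polyfit(voltages, np.log(counts), 1)[0]
        assert abs(1.0 / slope - km.voltage_scale) < 5.0


class TestConductanceSample:
    def test_single_component_mean(self):
        g = pp.sample_conductances(((1.1, 0.11, 1.0),), n=1000, seed=0)
        assert g.mean() == pytest.approx(1.1, abs=0.02)
        assert (g > 0).all()

    def test_component_proportions(self):
        g = pp.sample_conductances(n=5000, seed=1)
        frac_small = np.mean(g < 2.0)
        assert frac_small == pytest.approx(0.2, abs=0.03)

    @pytest.mark.parametrize(
        "mixture,n",
        [
            (((1.0, -0.1, 1.0),), 10),  # negative sd
            (((1.0, 0.1, 0.5),), 10),  # weights don't sum to 1
            (((1.0, 0.1, 1.0),), 0),  # empty sample
        ],
    )
    def test_invalid_inputs_rejected(self, mixture, n):
        with pytest.raises(ValueError):
            pp.sample_conductances(mixture, n=n, seed=0)

    def test_seeded_determinism(self):
        a = pp.sample_conductances(n=100, seed=7)
        b = pp.sample_conductances(n=100, seed=7)
        np.testing.assert_array_equal(a, b)
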