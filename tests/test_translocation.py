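"""Translocation statistics: frequency fits, bootstrap, peaks, ratios."""

import numpy as np
import pandas as pd
import pytest

import peptidepore as pp
from peptidepore.translocation import (
    BootstrapConfig,
    blockade_ratio,
    event_frequency,
    exact_bootstrap_means,
    molecular_volumes,
    scatter_peak,
    signal_to_noise,
)


def _events(durations, amplitudes):
    return [
        pp.EventRecord(0.1 * i, d, a, "blockade")
        for i, (d, a) in enumerate(zip(durations, amplitudes))
    ]


class TestFrequency:
    def test_count_over_duration(self):
        assert event_frequency(_events([1] * 30, [10] * 30), 60.0) == 0.5
        assert event_frequency([], 60.0) == 0.0

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            event_frequency([], 0.0)

    def test_seeded_stream_within_poisson_band(self):
        km = pp.KineticsModel()
        gt = pp.simulate_event_times(km, 100.0, 80.0, 300.0, seed=2)
        f = len(gt.events) / 300.0
        rate = km.event_rate(100.0, 80.0)
        assert abs(f - rate) < 4 * np.sqrt(rate / 300.0)


class TestKineticsFits:
    def test_exact_line_in_concentration(self):
        df = pd.DataFrame(
            {
                "concentration_nM": [50, 100, 150, 200],
                "voltage_mV": [80.0] * 4,
                "frequency_per_s": [0.5, 1.0, 1.5, 2.0],
            }
        )
        res = pp.fit_frequency_models(df, fixed_voltage_mV=80.0)
        assert res.concentration_fit.params["slope"] == pytest.approx(0.01)
        assert res.concentration_fit.r_squared == pytest.approx(1.0)

    def test_exact_exponential_in_voltage(self):
        voltages = [40.0, 60.0, 80.0, 100.0]
        df = pd.DataFrame(
            {
                "concentration_nM": [100.0] * 4,
                "voltage_mV": voltages,
                "frequency_per_s": [2.0 * np.exp(v / 25.0) for v in voltages],
            }
        )
        res = pp.fit_frequency_models(df, fixed_concentration_nM=100.0)
        assert res.voltage_fit.params["v0_mV"] == pytest.approx(25.0)
        assert res.voltage_fit.params["amplitude"] == pytest.approx(2.0)

    def test_noisy_sweep_recovers_generator(self):
        """Poisson-noisy frequencies over the 50-200 nM / 40-100 mV sweeps:
        fitted slope and v0 land within 2 SE of the generator's values."""
        km = pp.KineticsModel()
        rows = []
        for i, c in enumerate((50.0, 100.0, 150.0, 200.0)):
            gt = pp.simulate_event_times(km, c, 80.0, 600.0, seed=100 + i)
            rows.append({"concentration_nM": c, "voltage_mV": 80.0,
                         "frequency_per_s": len(gt.events) / 600.0})
        for i, v in enumerate((40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 100.0)):
            gt = pp.simulate_event_times(km, 100.0, v, 600.0, seed=200 + i)
            rows.append({"concentration_nM": 100.0, "voltage_mV": v,
                         "frequency_per_s": len(gt.events) / 600.0})
        res = pp.TranslocationKinetics(pd.DataFrame(rows)).fit(
            fixed_voltage_mV=80.0, fixed_concentration_nM=100.0
        )
        true_slope = km.capture_prefactor * np.exp(80.0 / km.voltage_scale)
        cf, vf = res.concentration_fit, res.voltage_fit
        assert abs(cf.params["slope"] - true_slope) < 2 * cf.stderr["slope"]
        assert abs(vf.params["v0_mV"] - km.voltage_scale) < 2 * vf.stderr["v0_mV"]

    def test_nonpositive_frequency_excluded_with_warning(self):
        df = pd.DataFrame(
            {
                "concentration_nM": [100.0] * 4,
                "voltage_mV": [40.0, 60.0, 80.0, 100.0],
                "frequency_per_s": [0.0, 1.0, 2.0, 4.0],
            }
        )
        with pytest.warns(UserWarning, match="excluded"):
            pp.fit_frequency_models(df, fixed_concentration_nM=100.0)


class TestBootstrap:
    def test_single_event_degenerate(self):
        res = exact_bootstrap_means(_events([2.0], [100.0]), BootstrapConfig(B=64, seed=0))
        assert np.all(res.mean_durations_ms == 2.0)
        assert np.all(res.mean_amplitudes_pA == 100.0)

    def test_grand_mean_matches_sample_mean(self):
        res = exact_bootstrap_means(
            _events([1.0, 3.0], [10.0, 30.0]), BootstrapConfig(B=4096, seed=1)
        )
        mc_se = np.std([1.0, 3.0]) / np.sqrt(2) / np.sqrt(4096)
        assert abs(res.mean_durations_ms.mean() - 2.0) < 3 * mc_se

    def test_full_scale_deterministic(self, dwell_amplitude_events):
        cfg = BootstrapConfig(B=65_536, seed=11)
        a = exact_bootstrap_means(dwell_amplitude_events[:100], cfg)
        b = exact_bootstrap_means(dwell_amplitude_events[:100], cfg)
        np.testing.assert_array_equal(a.mean_durations_ms, b.mean_durations_ms)
        assert a.B == 65_536

    def test_variance_contracts_by_n(self, dwell_amplitude_events):
        events = dwell_amplitude_events[:100]
        res = exact_bootstrap_means(events, BootstrapConfig(B=16_384, seed=2))
        d = np.array([e.duration_ms for e in events])
        expected = d.var() / d.size
        assert res.mean_durations_ms.var() == pytest.approx(expected, rel=0.1)

    def test_empty_events_rejected(self):
        with pytest.raises(ValueError):
            exact_bootstrap_means([], BootstrapConfig(B=8, seed=0))


class TestScatterPeak:
    def test_identical_pairs_return_that_pair(self):
        res = exact_bootstrap_means(_events([2.0], [100.0]), BootstrapConfig(B=64, seed=0))
        assert scatter_peak(res) == (2.0, 100.0)

    def test_few_pairs_fall_back_to_median(self):
        res = exact_bootstrap_means(
            _events([1.0, 2.0, 4.0], [10.0, 20.0, 40.0]), BootstrapConfig(B=5, seed=3)
        )
        with pytest.warns(UserWarning, match="median"):
            scatter_peak(res)

    def test_recovers_generator_modes(self, dwell_amplitude_events):
        """KDE peak of the bootstrap means within 5% of the generator's
        195 pA amplitude and 1.8 ms dwell scale."""
        res = exact_bootstrap_means(
            dwell_amplitude_events, BootstrapConfig(B=65_536, seed=4)
        )
        d, a = scatter_peak(res)
        assert abs(a - 195.0) / 195.0 < 0.05
        assert abs(d - 1.8) / 1.8 < 0.05
        assert res.bandwidths is not None

    def test_translation_equivariance(self, dwell_amplitude_events):
        events = dwell_amplitude_events[:100]
        shifted = [
            pp.EventRecord(e.start_s, e.duration_ms + 5.0, e.amplitude_pA + 50.0, e.kind)
            for e in events
        ]
        p0 = scatter_peak(exact_bootstrap_means(events, BootstrapConfig(B=8192, seed=5)))
        p1 = scatter_peak(exact_bootstrap_means(shifted, BootstrapConfig(B=8192, seed=5)))
        assert p1[0] - p0[0] == pytest.approx(5.0, abs=1e-9)
        assert p1[1] - p0[1] == pytest.approx(50.0, abs=1e-9)

    def test_bimodal_returns_taller_mode(self):
        rng = np.random.default_rng(6)
        d = np.concatenate([rng.normal(1.0, 0.05, 3000), rng.normal(3.0, 0.05, 1000)])
        a = np.concatenate([rng.normal(100, 2.0, 3000), rng.normal(300, 2.0, 1000)])
        res = pp.BootstrapResult(d, a, B=d.size, n=d.size)
        dpk, apk = scatter_peak(res)
        assert dpk == pytest.approx(1.0, abs=0.1)
        assert apk == pytest.approx(100.0, abs=5.0)


class TestRatiosAndSNR:
    def test_blockade_ratio(self):
        assert blockade_ratio(195.0, 669.0) == pytest.approx(0.29, abs=0.005)
        assert blockade_ratio(5.0, 5.0) == 1.0
        assert blockade_ratio(0.0, 5.0) == 0.0
        with pytest.raises(ValueError):
            blockade_ratio(1.0, 0.0)

    def test_molecular_volumes_defaults(self):
        v_ds, v_g4, ratio = molecular_volumes()
        assert v_ds == pytest.approx(np.pi * 4.0)  # pi r^2 L, r=1, L=4
        assert v_g4 == pytest.approx(29.2, rel=0.01)
        assert ratio == pytest.approx(0.43, abs=0.01)

    def test_volume_model_validated(self):
        with pytest.raises(ValueError):
            pp.VolumeModel(dsdna_radius_nm=-1.0)

    def test_signal_to_noise(self):
        events = _events([1.0] * 10, [50.0] * 10)
        assert signal_to_noise(events, 5.0) == 10.0
        with pytest.raises(ValueError):
            signal_to_noise([], 5.0)
        with pytest.raises(ValueError):
            signal_to_noise(events, 0.0)

    def test_snr_ordering_between_pores(self):
        """A quieter pore gives the larger SNR for the same blockades."""
        events = _events([1.0] * 20, [60.0] * 20)
        assert signal_to_noise(events, 2.0) > signal_to_noise(events, 8.0)
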