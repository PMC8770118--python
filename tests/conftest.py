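import numpy as np
import pytest

import peptidepore as pp

#: class weights used for the seeded classification ensemble: stable
#: (step + square-top) weight 0.67, matching the optimized recording mix
ENSEMBLE_WEIGHTS = {
    "step": 0.335,
    "square-top": 0.335,
    "multi-level": 0.165,
    "erratic": 0.165,
}


def make_signal(label: str, noise_sd: float, seed: int):
    morph = pp.SignalMorphology(label, level_count=3 if label == "multi-level" else 1)
    return pp.simulate_insertion_signal(
        morph, unit_conductance_nS=1.1, voltage_mV=100.0, noise_sd=noise_sd, seed=seed
    )


@pytest.fixture(scope="session")
def classified_ensemble():
    """1,000 seeded signals at SNR 11 (110 pA step, 10 pA noise): true labels
    drawn with stable weight 0.67, plus the classifier's calls."""
    rng = np.random.default_rng(20240917)
    labels = list(ENSEMBLE_WEIGHTS)
    probs = np.array([ENSEMBLE_WEIGHTS[k] for k in labels])
    true_labels = []
    calls = []
    for _ in range(1000):
        lab = labels[int(rng.choice(len(labels), p=probs))]
        trace, _ = make_signal(lab, noise_sd=10.0, seed=int(rng.integers(2**31)))
        true_labels.append(lab)
        calls.append(pp.classify_trace(trace, noise_sd=10.0))
    return true_labels, calls


@pytest.fixture(scope="session")
def dwell_amplitude_events():
    """400 translocation events drawn at the default kinetics (amplitude
    195 +/- 20 pA, mean dwell 1.8 ms at the dwell-peak voltage)."""
    km = pp.KineticsModel()
    duration = 400 / km.event_rate(100.0, 80.0)
    truth = pp.simulate_event_times(km, 100.0, 80.0, duration, seed=3)
    return [
        pp.EventRecord(e.start_s, e.duration_ms, e.amplitude_pA, "blockade")
        for e in truth.events
    ]
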