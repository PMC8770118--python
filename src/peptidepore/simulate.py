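"""Synthetic channel-current generator.

Stands in for patch-clamp recordings of peptide nanopores in a planar lipid
bilayer: baseline noise with a low-pass filter character, pore-insertion
signals of the four canonical morphologies (step, square-top, multi-level,
erratic), conductance samples from a multi-component mixture, and analyte
translocation event streams with Poisson capture kinetics.

Conventions
-----------
* currents in pA, voltages in mV, conductances in nS, dwell times in ms;
* sampling at 20 kHz with a 4 kHz low-pass filter unless overridden;
* the low-pass filter is applied to the generated noise only, so planted
  amplitudes and transition times stay exact in the ground truth;
* every generator is a pure function of its arguments plus the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .trace import GroundTruth, Trace, TrueEvent

__all__ = [
    "KineticsModel",
    "SignalMorphology",
    "MORPHOLOGY_LABELS",
    "DEFAULT_SAMPLING_HZ",
    "DEFAULT_CUTOFF_HZ",
    "DEFAULT_CONDUCTANCE_MIXTURE",
    "simulate_noise_trace",
    "simulate_insertion_signal",
    "simulate_event_stream",
    "simulate_event_times",
    "sample_conductances",
]

DEFAULT_SAMPLING_HZ = 20_000.0
DEFAULT_CUTOFF_HZ = 4_000.0

MORPHOLOGY_LABELS = ("step", "square-top", "multi-level", "erratic")

#: Equal-weight mixture at the five conductance peaks of the multidisperse
#: SV28 pore (nS), sd = 10% of each mean.
DEFAULT_CONDUCTANCE_MIXTURE = tuple(
    (m, 0.1 * m, 0.2) for m in (1.1, 3.3, 7.0, 10.5, 14.4)
)


@dataclass
class KineticsModel:
    """Capture and dwell kinetics of analyte translocation.

    Event arrivals are Poisson with rate ``k0 * C * exp(V / v0)`` — linear in
    analyte concentration and exponential in applied voltage.  The mean dwell
    is unimodal in voltage, ``mu_max * (V / Vp) * exp(1 - V / Vp)``, peaking
    at ``Vp`` (low voltages reject the analyte from the pore; high voltages
    sweep it through quickly).  Dwell times are log-normal with log-scale sd
    ``dwell_dispersion``; blockade amplitudes are Gaussian.
    """

    capture_prefactor: float = 4e-4  # events / s / nM at V = 0
    voltage_scale: float = 25.0  # mV
    dwell_peak_voltage: float = 80.0  # mV
    dwell_peak_mean: float = 1.8  # ms
    amplitude_mean: float = 195.0  # pA
    amplitude_sd: float = 20.0  # pA
    dwell_dispersion: float = 0.4  # log-scale sd

    def __post_init__(self) -> None:
        for name in (
            "capture_prefactor",
            "voltage_scale",
            "dwell_peak_voltage",
            "dwell_peak_mean",
            "amplitude_mean",
            "amplitude_sd",
            "dwell_dispersion",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def event_rate(self, concentration_nM: float, voltage_mV: float) -> float:
        """Poisson capture rate (events/s)."""
        if concentration_nM < 0:
            raise ValueError("concentration must be >= 0")
        return (
            self.capture_prefactor
            * concentration_nM
            * np.exp(voltage_mV / self.voltage_scale)
        )

    def mean_dwell(self, voltage_mV: float) -> float:
        """Mean dwell time (ms) at a given voltage; peaks at Vp."""
        v = voltage_mV / self.dwell_peak_voltage
        return self.dwell_peak_mean * v * np.exp(1.0 - v)


@dataclass
class SignalMorphology:
    """Shape parameters for one insertion signal.

    ``level_count`` is the number of distinct above-baseline levels; for
    step and square-top morphologies the dwell of each level is
    ``level_dwell_ms``; erratic signals fluctuate with correlation time
    ``erratic_tau_ms`` and never hold a level.
    """

    label: str
    level_count: int = 1
    level_dwell_ms: float = 60.0
    first_transition_s: float = 0.05
    erratic_tau_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in MORPHOLOGY_LABELS:
            raise ValueError(
                f"unknown morphology {self.label!r}; expected one of {MORPHOLOGY_LABELS}"
            )
        if self.level_count < 1:
            raise ValueError("level_count must be >= 1")
        if self.label == "multi-level" and self.level_count < 2:
            raise ValueError("multi-level morphology needs >= 2 levels")
        if self.level_dwell_ms <= 0 or self.erratic_tau_ms <= 0:
            raise ValueError("dwell and correlation times must be positive")


def _filtered_noise(
    n: int,
    sampling_rate: float,
    noise_sd: float,
    cutoff_hz: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """White Gaussian noise low-passed by a 4-pole Bessel filter.

    The filtered record is rescaled so its RMS equals ``noise_sd`` exactly:
    the configured value is the *post-filter* noise level, as it would be
    read off a recording.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0 or n == 0:
        return np.zeros(n)
    x = rng.standard_normal(n)
    if cutoff_hz and cutoff_hz < sampling_rate / 2:
        sos = _signal.bessel(4, cutoff_hz, "low", fs=sampling_rate, output="sos")
        x = _signal.sosfiltfilt(sos, x)
    s = x.std()
    if s > 0:
        x = x * (noise_sd / s)
    return x


def simulate_noise_trace(
    duration_s: float,
    sampling_rate: float = DEFAULT_SAMPLING_HZ,
    noise_sd: float = 5.0,
    baseline_pA: float = 0.0,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    voltage_mV: float = 100.0,
    seed: int | None = None,
) -> Trace:
    """Baseline trace: constant level plus filtered Gaussian noise."""
    if duration_s <= 0 or sampling_rate <= 0:
        raise ValueError(
            f"duration and sampling rate must be positive "
            f"(got {duration_s} s at {sampling_rate} Hz)"
        )
    n = int(round(duration_s * sampling_rate))
    rng = np.random.default_rng(seed)
    current = baseline_pA + _filtered_noise(n, sampling_rate, noise_sd, cutoff_hz, rng)
    return Trace(current, sampling_rate, voltage_mV, label="noise")


def _ideal_levels(
    morphology: SignalMorphology, step_pA: float, duration_s: float
) -> list[tuple[float, float]]:
    """(start_s, level_pA) breakpoints for the deterministic part."""
    t0 = morphology.first_transition_s
    dw = morphology.level_dwell_ms / 1000.0
    if morphology.label == "step":
        return [(t0 + i * dw, (i + 1) * step_pA) for i in range(morphology.level_count)]
    if morphology.label == "square-top":
        out = []
        t = t0
        for _ in range(morphology.level_count):
            out.append((t, step_pA))
            out.append((t + dw, 0.0))
            t += 2 * dw
        return out
    if morphology.label == "multi-level":
        k = morphology.level_count
        # rise to L1, jump to the top level, then step down to an
        # intermediate level: guarantees both up and down transitions and
        # exactly k distinct above-baseline levels without returning square-wise
        order = [1, k] + list(range(k - 1, 1, -1)) if k >= 2 else [1]
        return [(t0 + i * dw, lev * step_pA) for i, lev in enumerate(order)]
    raise ValueError(f"no deterministic level plan for {morphology.label!r}")


def simulate_insertion_signal(
    morphology: SignalMorphology,
    unit_conductance_nS: float,
    voltage_mV: float = 100.0,
    noise_sd: float = 2.0,
    duration_s: float = 0.4,
    sampling_rate: float = DEFAULT_SAMPLING_HZ,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    baseline_pA: float = 0.0,
    seed: int | None = None,
) -> tuple[Trace, GroundTruth]:
    """One pore-insertion signal of the requested morphology.

    Level amplitudes are multiples of the unit current step
    ``dI = g * V`` (nS * mV = pA).  The ground truth records every planted
    transition and the morphology label.
    """
    if unit_conductance_nS <= 0:
        raise ValueError("unit_conductance must be positive")
    if duration_s <= 0 or sampling_rate <= 0:
        raise ValueError("duration and sampling rate must be positive")
    step_pA = unit_conductance_nS * voltage_mV
    n = int(round(duration_s * sampling_rate))
    rng = np.random.default_rng(seed)
    ideal = np.full(n, baseline_pA)
    truth = GroundTruth(label=morphology.label, seed=seed)

    if morphology.label == "erratic":
        # Ornstein-Uhlenbeck-like fluctuation around half the unit step:
        # the current is raised but never holds a resolvable level.
        i0 = int(round(morphology.first_transition_s * sampling_rate))
        tau = morphology.erratic_tau_ms / 1000.0
        dt = 1.0 / sampling_rate
        alpha = np.exp(-dt / tau)
        sd_ou = step_pA / 3.0
        m = n - i0
        innov = rng.standard_normal(m) * sd_ou * np.sqrt(1 - alpha**2)
        # lfilter implements the AR(1) recursion without a python loop
        x = _signal.lfilter([1.0], [1.0, -alpha], innov)
        ideal[i0:] = baseline_pA + step_pA / 2.0 + x
        np.clip(ideal, baseline_pA, None, out=ideal)
        truth.events.append(
            TrueEvent(
                start_s=morphology.first_transition_s,
                duration_ms=(n - i0) / sampling_rate * 1000.0,
                amplitude_pA=step_pA / 2.0,
                kind="insertion",
                label="erratic",
            )
        )
    else:
        plan = _ideal_levels(morphology, step_pA, duration_s)
        prev_level = 0.0
        for j, (t, level) in enumerate(plan):
            i = int(round(t * sampling_rate))
            if i >= n:
                break
            ideal[i:] = baseline_pA + level
            stop = plan[j + 1][0] if j + 1 < len(plan) else duration_s
            truth.events.append(
                TrueEvent(
                    start_s=t,
                    duration_ms=(min(stop, duration_s) - t) * 1000.0,
                    amplitude_pA=level - prev_level,
                    kind="insertion",
                    label=morphology.label,
                )
            )
            prev_level = level

    noise = _filtered_noise(n, sampling_rate, noise_sd, cutoff_hz, rng)
    trace = Trace(ideal + noise, sampling_rate, voltage_mV, label=morphology.label)
    return trace, truth


def simulate_event_times(
    kinetics: KineticsModel,
    concentration_nM: float,
    voltage_mV: float,
    duration_s: float,
    seed: int | None = None,
) -> GroundTruth:
    """Translocation event list (no trace): Poisson arrivals, log-normal
    dwells with voltage-dependent mean, Gaussian amplitudes."""
    if concentration_nM < 0:
        raise ValueError("concentration must be >= 0")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    rate = kinetics.event_rate(concentration_nM, voltage_mV)
    truth = GroundTruth(label="blockade-stream", seed=seed)
    if rate == 0:
        return truth
    n_exp = rate * duration_s
    n_ev = rng.poisson(n_exp)
    starts = np.sort(rng.uniform(0.0, duration_s, size=n_ev))
    mu = kinetics.mean_dwell(voltage_mV)
    s = kinetics.dwell_dispersion
    # log-normal parameterized by its mean: E[x] = exp(m + s^2/2)
    m = np.log(mu) - 0.5 * s * s
    dwells = rng.lognormal(m, s, size=n_ev)
    amps = np.abs(rng.normal(kinetics.amplitude_mean, kinetics.amplitude_sd, size=n_ev))
    for t, d, a in zip(starts, dwells, amps):
        truth.events.append(
            TrueEvent(start_s=float(t), duration_ms=float(d), amplitude_pA=float(a), kind="blockade")
        )
    return truth


def simulate_event_stream(
    kinetics: KineticsModel,
    concentration_nM: float,
    voltage_mV: float,
    duration_s: float,
    open_current_pA: float,
    noise_sd: float = 5.0,
    sampling_rate: float = DEFAULT_SAMPLING_HZ,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    seed: int | None = None,
) -> tuple[Trace, GroundTruth]:
    """Open-pore trace with analyte blockades planted per the kinetics model.

    Overlapping blockades add their depths (as concurrent occupancies
    would); the ground truth lists every planted event.
    """
    truth = simulate_event_times(kinetics, concentration_nM, voltage_mV, duration_s, seed)
    n = int(round(duration_s * sampling_rate))
    ideal = np.full(n, float(open_current_pA))
    for ev in truth.events:
        i = int(round(ev.start_s * sampling_rate))
        j = min(n, i + max(1, int(round(ev.duration_ms / 1000.0 * sampling_rate))))
        ideal[i:j] -= ev.amplitude_pA
    rng = np.random.default_rng(None if seed is None else seed + 1)
    noise = _filtered_noise(n, sampling_rate, noise_sd, cutoff_hz, rng)
    trace = Trace(ideal + noise, sampling_rate, voltage_mV, label="blockade-stream")
    return trace, truth


def sample_conductances(
    mixture: tuple[tuple[float, float, float], ...] = DEFAULT_CONDUCTANCE_MIXTURE,
    n: int = 1000,
    seed: int | None = None,
) -> np.ndarray:
    """Draw insertion conductances (nS) from a Gaussian mixture.

    ``mixture`` is a sequence of ``(mean, sd, weight)`` components; weights
    must sum to 1.  Negative draws are rejected and redrawn, so the sample
    is strictly positive.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mixture = tuple(mixture)
    means = np.array([m for m, _, _ in mixture])
    sds = np.array([s for _, s, _ in mixture])
    weights = np.array([w for _, _, w in mixture])
    if (sds < 0).any():
        raise ValueError("component sd must be >= 0")
    if (means <= 0).any():
        raise ValueError("component means must be positive")
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError(f"mixture weights must sum to 1, got {weights.sum()}")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(mixture), size=n, p=weights / weights.sum())
    out = rng.normal(means[comp], sds[comp])
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(means[comp[bad]], sds[comp[bad]])
        bad = out <= 0
    return out
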