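"""Baseline estimation and detection of insertion steps and blockade events.

The open-channel conductance of a pore is the initial current step from the
baseline (~0 A) divided by the applied voltage; analyte translocations are
transient excursions below the open-pore level.
"""

from __future__ import annotations

import warnings

import numpy as np

from .classify import idealize_levels
from .trace import EventRecord, Trace

__all__ = [
    "estimate_baseline",
    "detect_insertion_steps",
    "detect_blockade_events",
]

DEFAULT_K_SIGMA = 5.0
DEFAULT_MIN_DWELL_MS = 0.5


def estimate_baseline(trace: Trace) -> tuple[float, float]:
    """Dominant-level baseline (pA) and noise sd (pA).

    The baseline is the mode of a current histogram refined by the median of
    samples near the modal bin, so a trace spending most of its time at the
    closed level is unaffected by open-pore excursions.  The noise sd is the
    10th percentile of windowed standard deviations: a low-variance-segment
    estimate robust to steps and events.
    """
    x = trace.current
    if x.size == 0:
        raise ValueError("cannot estimate a baseline from an empty trace")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return float(lo), 0.0
    counts, edges = np.histogram(x, bins=min(200, max(10, x.size // 10)))
    k = int(np.argmax(counts))
    width = edges[1] - edges[0]
    center = 0.5 * (edges[k] + edges[k + 1])
    near = x[np.abs(x - center) <= 1.5 * width]
    baseline = float(np.median(near)) if near.size else float(center)

    win = max(8, int(round(0.010 * trace.sampling_rate)))  # ~10 ms windows
    nwin = x.size // win
    if nwin >= 2:
        stds = x[: nwin * win].reshape(nwin, win).std(axis=1)
        noise_sd = float(np.median(stds))
    else:
        noise_sd = float(x.std())
    return baseline, noise_sd


def detect_insertion_steps(
    trace: Trace,
    min_dwell_ms: float = DEFAULT_MIN_DWELL_MS,
    k_sigma: float = DEFAULT_K_SIGMA,
    baseline: float | None = None,
    noise_sd: float | None = None,
) -> list[EventRecord]:
    """Upward level transitions interpreted as pore insertions.

    A transition qualifies when its amplitude exceeds ``k_sigma`` times the
    noise sd and the new level persists at least ``min_dwell_ms``.  Each
    event carries the per-step conductance ``g = dI / V`` (nS); the first
    step taken from the baseline is flagged ``initial``.
    """
    if noise_sd is None:
        _, noise_sd = estimate_baseline(trace)
    ideal = idealize_levels(trace, noise_sd=noise_sd, min_dwell_ms=min_dwell_ms)
    if baseline is None and ideal.segments:
        # an insertion trace starts at the closed-bilayer level, so the
        # first idealized level is the baseline the initial step leaves
        baseline = ideal.segments[0].level_pA
    thr = k_sigma * noise_sd
    if noise_sd == 0:
        thr = 1e-9
    tol = 3.0 * noise_sd if noise_sd > 0 else 1e-9

    if trace.voltage in (None, 0):
        warnings.warn(
            "applied voltage is zero or unknown; insertion conductance omitted",
            stacklevel=2,
        )

    out: list[EventRecord] = []
    segs = ideal.segments
    initial_seen = False
    for prev, cur in zip(segs[:-1], segs[1:]):
        delta = cur.level_pA - prev.level_pA
        if delta <= thr or cur.dwell_ms < min_dwell_ms:
            continue
        flags: tuple[str, ...] = ()
        if not initial_seen and abs(prev.level_pA - baseline) <= tol:
            flags = ("initial",)
            initial_seen = True
        g = None
        if trace.voltage not in (None, 0):
            g = delta / trace.voltage
        out.append(
            EventRecord(
                start_s=cur.start_s,
                duration_ms=cur.dwell_ms,
                amplitude_pA=float(delta),
                kind="insertion",
                conductance_nS=g,
                flags=flags,
            )
        )
    return out


def detect_blockade_events(
    trace: Trace,
    open_level_pA: float,
    threshold_fraction: float = 0.1,
    min_dwell_ms: float = DEFAULT_MIN_DWELL_MS,
    noise_sd: float | None = None,
) -> list[EventRecord]:
    """Analyte blockades: excursions below the open-pore current.

    Contiguous runs of samples more than ``threshold_fraction * open_level``
    below the open level, lasting at least ``min_dwell_ms``, become blockade
    events with duration equal to the excursion length and amplitude equal
    to the mean depth below the open level (mean rather than maximum, for
    noise robustness).  Events containing a second resolvable blocked level
    — concurrent translocation of multiple molecules — are flagged
    ``nested``; no deconvolution is attempted.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError(f"threshold_fraction must be in (0, 1), got {threshold_fraction}")
    x = trace.current
    fs = trace.sampling_rate
    if noise_sd is None:
        _, noise_sd = estimate_baseline(trace)
    thr_level = open_level_pA * (1.0 - threshold_fraction)
    below = x < thr_level
    if not below.any():
        return []
    idx = np.flatnonzero(below)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = [idx[0], *idx[breaks + 1]]
    run_stops = [*idx[breaks], idx[-1]]
    min_n = max(1, int(round(min_dwell_ms / 1000.0 * fs)))
    out: list[EventRecord] = []
    for a, b in zip(run_starts, run_stops):
        b = b + 1  # exclusive stop
        if b - a < min_n:
            continue
        depth = float(open_level_pA - x[a:b].mean())
        flags: tuple[str, ...] = ()
        if b - a >= 4 * min_n and noise_sd >= 0:
            sub = idealize_levels(
                trace.segment(a / fs, b / fs), noise_sd=max(noise_sd, 1e-9),
                min_dwell_ms=min_dwell_ms,
            )
            if len(sub.distinct_levels()) >= 2:
                flags = ("nested",)
        out.append(
            EventRecord(
                start_s=a / fs,
                duration_ms=(b - a) / fs * 1000.0,
                amplitude_pA=max(depth, 0.0),
                kind="blockade",
                flags=flags,
            )
        )
    return out
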