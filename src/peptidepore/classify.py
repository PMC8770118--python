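"""Signal idealization and the four-way insertion-signal taxonomy.

Insertion signals are idealized into piecewise-constant levels by binary
change-point segmentation, then classified as one of four morphologies:

* ``step`` — only upward transitions between resolvable levels; the final
  level persists to the end of the segment;
* ``square-top`` — the current rises and returns to within tolerance of the
  pre-event level before the segment ends;
* ``multi-level`` — at least three resolvable levels with both upward and
  downward transitions that do not return square-wise;
* ``erratic`` — no level holds for the minimum dwell, or the residual after
  idealization is large compared with the baseline noise.

Step and square-top signals indicate stable pore formation; multi-level and
erratic signals indicate unstable pores.  When definitions overlap, the
precedence is erratic > multi-level > square-top > step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .trace import Trace

__all__ = [
    "IdealizedSignal",
    "ClassifiedSignal",
    "idealize_levels",
    "classify_signal",
    "classify_trace",
    "stable_fraction",
    "STABLE_CLASSES",
    "UNSTABLE_CLASSES",
]

STABLE_CLASSES = ("step", "square-top")
UNSTABLE_CLASSES = ("multi-level", "erratic")

#: adjacent idealized levels closer than this many noise sd are merged
MERGE_SD = 3.0


@dataclass
class Level:
    """One piecewise-constant segment of an idealized signal."""

    start_s: float
    dwell_ms: float
    level_pA: float


@dataclass
class IdealizedSignal:
    """Piecewise-constant idealization of a trace segment."""

    segments: list[Level] = field(default_factory=list)
    residual_rms: float = 0.0
    noise_sd: float = 0.0
    min_dwell_ms: float = 0.5

    @property
    def levels(self) -> list[Level]:
        """Segments that persist at least the minimum dwell ("resolvable")."""
        return [s for s in self.segments if s.dwell_ms >= self.min_dwell_ms]

    def distinct_levels(self, tol_pA: float | None = None) -> list[float]:
        """Resolvable level values, clustered within ``tol_pA`` (default
        3 x noise sd)."""
        if tol_pA is None:
            tol_pA = max(MERGE_SD * self.noise_sd, 1e-9)
        vals = sorted(s.level_pA for s in self.levels)
        out: list[list[float]] = []
        for v in vals:
            if out and v - np.mean(out[-1]) <= tol_pA:
                out[-1].append(v)
            else:
                out.append([v])
        return [float(np.mean(c)) for c in out]


@dataclass
class ClassifiedSignal:
    """Morphology label plus the derived stability call."""

    label: str
    stability: str

    def __post_init__(self) -> None:
        expect = "stable" if self.label in STABLE_CLASSES else "unstable"
        if self.stability != expect:
            raise ValueError(f"{self.label} signals must be {expect}")


def _binary_segmentation(
    x: np.ndarray, noise_sd: float, min_size: int
) -> list[int]:
    """Change points by recursive binary segmentation on segment means.

    A split is accepted when the mean difference across it both exceeds the
    merge tolerance and is statistically large for the segment lengths
    involved (the z threshold is inflated for the correlation the 4 kHz
    filter introduces at 20 kHz sampling).
    """
    n = x.size
    csum = np.concatenate([[0.0], np.cumsum(x)])
    # effective decorrelation of low-passed noise: ~fs / (2 * cutoff)
    corr_inflate = np.sqrt(2.5)
    abs_thr = max(MERGE_SD * noise_sd, 1e-9)
    cps: list[int] = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2 * min_size:
            continue
        ks = np.arange(lo + min_size, hi - min_size + 1)
        nl = ks - lo
        nr = hi - ks
        mean_l = (csum[ks] - csum[lo]) / nl
        mean_r = (csum[hi] - csum[ks]) / nr
        diff = mean_l - mean_r
        gain = nl * nr / (hi - lo) * diff**2
        i = int(np.argmax(gain))
        k = int(ks[i])
        d = abs(float(diff[i]))
        se = noise_sd * np.sqrt(1.0 / nl[i] + 1.0 / nr[i]) * corr_inflate
        if d > abs_thr and (noise_sd == 0 or d > 5.0 * se):
            cps.append(k)
            stack.append((lo, k))
            stack.append((k, hi))
    return sorted(cps)


def idealize_levels(
    segment: Trace,
    noise_sd: float,
    min_dwell_ms: float = 0.5,
) -> IdealizedSignal:
    """Fit a piecewise-constant idealization to a trace segment.

    Adjacent fitted levels closer than ``3 * noise_sd`` are merged.  The
    residual RMS against the idealization is reported so downstream
    classification can recognize signals that no level structure explains.
    """
    x = segment.current
    if x.size == 0:
        raise ValueError("cannot idealize an empty segment")
    fs = segment.sampling_rate
    min_dwell_n = max(1, int(round(min_dwell_ms / 1000.0 * fs)))
    # allow levels shorter than the resolvable dwell so that erratic
    # fluctuation is fitted (and then rejected) rather than averaged away
    min_size = max(2, min_dwell_n // 4)
    cps = _binary_segmentation(x, noise_sd, min_size)
    bounds = [0, *cps, x.size]
    segs: list[tuple[int, int, float]] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        segs.append((a, b, float(x[a:b].mean())))
    # merge adjacent levels closer than the tolerance
    tol = max(MERGE_SD * noise_sd, 1e-9)
    merged: list[tuple[int, int, float]] = []
    for a, b, m in segs:
        if merged and abs(m - merged[-1][2]) < tol:
            pa, pb, pm = merged.pop()
            w1, w2 = pb - pa, b - a
            merged.append((pa, b, (pm * w1 + m * w2) / (w1 + w2)))
        else:
            merged.append((a, b, m))
    ideal = np.empty_like(x)
    levels = []
    for a, b, m in merged:
        ideal[a:b] = m
        levels.append(Level(start_s=a / fs, dwell_ms=(b - a) / fs * 1000.0, level_pA=m))
    rms = float(np.sqrt(np.mean((x - ideal) ** 2)))
    return IdealizedSignal(
        segments=levels, residual_rms=rms, noise_sd=noise_sd, min_dwell_ms=min_dwell_ms
    )


def classify_signal(ideal: IdealizedSignal) -> ClassifiedSignal:
    """Assign one of the four morphologies to an idealized signal."""
    tol = max(MERGE_SD * ideal.noise_sd, 1e-9)
    res = ideal.levels
    noisy_residual = ideal.noise_sd > 0 and ideal.residual_rms > MERGE_SD * ideal.noise_sd
    if not res or noisy_residual:
        return ClassifiedSignal("erratic", "unstable")

    values = [s.level_pA for s in res]
    ups = sum(1 for a, b in zip(values[:-1], values[1:]) if b - a > tol)
    downs = sum(1 for a, b in zip(values[:-1], values[1:]) if a - b > tol)
    n_distinct = len(ideal.distinct_levels())
    first, last = values[0], values[-1]
    rose = max(values) - first > tol
    returned = abs(last - first) <= tol

    if n_distinct >= 3 and ups and downs:
        return ClassifiedSignal("multi-level", "unstable")
    if rose and returned and downs:
        return ClassifiedSignal("square-top", "stable")
    last_persists = ideal.segments and ideal.segments[-1].dwell_ms >= ideal.min_dwell_ms
    if ups and not downs and last_persists:
        return ClassifiedSignal("step", "stable")
    return ClassifiedSignal("erratic", "unstable")


def classify_trace(
    trace: Trace, noise_sd: float, min_dwell_ms: float = 0.5
) -> ClassifiedSignal:
    """Idealize then classify in one call."""
    return classify_signal(idealize_levels(trace, noise_sd, min_dwell_ms))


def stable_fraction(labels: Sequence[ClassifiedSignal | str]) -> float:
    """Fraction of signals reflecting stable pore formation.

    Accepts :class:`ClassifiedSignal` objects or bare class labels; the
    result equals the mean of the per-signal stability indicators.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("stable_fraction of an empty ensemble is undefined")
    n_stable = 0
    for item in labels:
        lab = item.label if isinstance(item, ClassifiedSignal) else item
        if lab not in STABLE_CLASSES + UNSTABLE_CLASSES:
            raise ValueError(f"unknown class label {lab!r}")
        n_stable += lab in STABLE_CLASSES
    return n_stable / len(labels)
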