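"""Core containers for single-channel current recordings and detected events.

A :class:`Trace` is a uniformly sampled current record (pA) together with the
applied transmembrane voltage (mV) needed to convert current steps into
conductances.  An :class:`EventRecord` is one detected feature of the trace:
either a pore-insertion step or an analyte blockade.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Trace", "EventRecord", "TrueEvent", "GroundTruth"]


@dataclass
class Trace:
    """Uniformly sampled channel current.

    Parameters
    ----------
    current : ndarray
        Current samples in pA.
    sampling_rate : float
        Sampling frequency in Hz (> 0).
    voltage : float or None
        Applied voltage in mV.  ``None`` means unknown; conductance
        conversion is then impossible.
    label : str
        Free-text provenance (scenario name, file of origin, ...).
    """

    current: np.ndarray
    sampling_rate: float
    voltage: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.current = np.asarray(self.current, dtype=float)
        if self.current.ndim != 1:
            raise ValueError("trace must be one-dimensional")
        if not np.isfinite(self.current).all():
            raise ValueError("trace contains non-finite samples")
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")

    def __len__(self) -> int:
        return self.current.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.current.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.current.size) / self.sampling_rate

    def segment(self, start_s: float, stop_s: float) -> "Trace":
        """Return the sub-trace between two times (seconds)."""
        i = max(0, int(round(start_s * self.sampling_rate)))
        j = min(len(self), int(round(stop_s * self.sampling_rate)))
        if j <= i:
            raise ValueError("empty segment requested")
        return replace(self, current=self.current[i:j])


@dataclass
class EventRecord:
    """One detected insertion step or blockade event.

    ``amplitude_pA`` is the positive magnitude of the current deviation
    (upward for insertions, downward for blockades).  ``conductance_nS`` is
    ``amplitude / voltage`` and is populated for insertions only.
    """

    start_s: float
    duration_ms: float
    amplitude_pA: float
    kind: str  # "insertion" | "blockade"
    conductance_nS: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("event duration must be positive")
        if self.amplitude_pA < 0:
            raise ValueError("event amplitude is a magnitude and must be >= 0")
        if self.kind not in ("insertion", "blockade"):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class TrueEvent:
    """A generator-planted transition, for ground-truth comparisons."""

    start_s: float
    duration_ms: float
    amplitude_pA: float
    kind: str
    label: str = ""


@dataclass
class GroundTruth:
    """Everything a simulator planted in a trace, keyed by its seed."""

    events: list[TrueEvent] = field(default_factory=list)
    label: str = ""
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.events)
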