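"""Plain-text file formats: trace TSV + YAML sidecar, event CSV, configs.

Trace files are two-column TSV (``time_s``, ``current_pA``) with a YAML
sidecar (same stem, ``.yaml``) carrying ``voltage_mV`` and ``sampling_hz``
and optionally ``seed`` and ``label``.  Event tables are CSV with columns
``start_s,duration_ms,amplitude_pA,kind,conductance_nS,flags``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .trace import EventRecord, Trace

__all__ = [
    "write_trace",
    "read_trace",
    "write_events",
    "read_events",
    "load_config",
    "save_config",
]

SIDECAR_KEYS = ("voltage_mV", "sampling_hz")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def write_trace(trace: Trace, path, seed: int | None = None) -> Path:
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.times, "current_pA": trace.current})
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    meta = {
        "voltage_mV": trace.voltage,
        "sampling_hz": trace.sampling_rate,
        "label": trace.label,
    }
    if seed is not None:
        meta["seed"] = seed
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh)
    return path


def read_trace(path) -> Trace:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"trace sidecar {sidecar} not found; it must define {SIDECAR_KEYS}"
        )
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh) or {}
    missing = [k for k in SIDECAR_KEYS if k not in meta]
    if missing:
        raise KeyError(f"trace sidecar {sidecar} lacks required keys: {missing}")
    df = pd.read_csv(path, sep="\t")
    if "current_pA" not in df.columns:
        raise ValueError(f"{path} is not a trace TSV (no current_pA column)")
    bad = df.index[df["current_pA"].isna()].tolist()
    if bad:
        # +2: header line plus 1-based numbering
        raise ValueError(f"{path}: malformed rows at lines {[i + 2 for i in bad[:10]]}")
    return Trace(
        df["current_pA"].to_numpy(),
        sampling_rate=float(meta["sampling_hz"]),
        voltage=None if meta["voltage_mV"] is None else float(meta["voltage_mV"]),
        label=str(meta.get("label", "")),
    )


def write_events(events: list[EventRecord], path) -> Path:
    path = Path(path)
    rows = [
        {
            "start_s": e.start_s,
            "duration_ms": e.duration_ms,
            "amplitude_pA": e.amplitude_pA,
            "kind": e.kind,
            "conductance_nS": e.conductance_nS,
            "flags": ";".join(e.flags),
        }
        for e in events
    ]
    cols = ["start_s", "duration_ms", "amplitude_pA", "kind", "conductance_nS", "flags"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    return path


def read_events(path) -> list[EventRecord]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        g = r.get("conductance_nS")
        flags = r.get("flags")
        out.append(
            EventRecord(
                start_s=float(r["start_s"]),
                duration_ms=float(r["duration_ms"]),
                amplitude_pA=float(r["amplitude_pA"]),
                kind=str(r["kind"]),
                conductance_nS=None if pd.isna(g) else float(g),
                flags=tuple(str(flags).split(";")) if isinstance(flags, str) and flags else (),
            )
        )
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return path
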