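"""End-to-end reproducible analysis runs.

``run_pipeline`` drives the full chain — simulate (optional) -> detect ->
classify -> conductance peaks -> geometry calibration -> translocation
statistics — writing every artifact (plus the config and derived seeds)
into an output directory.  Reruns with the same config produce identical
numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .calibration import HilleParams, PoreCalibration, hille_diameter
from .classify import classify_trace, stable_fraction
from .events import detect_blockade_events
from .io import save_config, write_events, write_trace
from .peaks import ConductancePeakModel
from .simulate import (
    DEFAULT_CONDUCTANCE_MIXTURE,
    KineticsModel,
    SignalMorphology,
    sample_conductances,
    simulate_event_stream,
    simulate_insertion_signal,
)
from .translocation import (
    BootstrapConfig,
    event_frequency,
    exact_bootstrap_means,
    scatter_peak,
    signal_to_noise,
)

__all__ = ["default_config", "run_pipeline"]


def default_config() -> dict:
    """The bundled demo configuration (all-synthetic inputs)."""
    return {
        "seed": 7,
        "simulate": {
            "n_signals": 40,
            "class_weights": {
                "step": 0.335,
                "square-top": 0.335,
                "multi-level": 0.165,
                "erratic": 0.165,
            },
            "unit_conductance_nS": 1.1,
            "voltage_mV": 100.0,
            "noise_sd_pA": 5.0,
            "conductance_sample_n": 2000,
            "event_stream": {
                "concentration_nM": 100.0,
                "voltage_mV": 100.0,
                "duration_s": 30.0,
                "open_current_pA": 1050.0,
            },
        },
        "detection": {"k_sigma": 5.0, "min_dwell_ms": 0.5, "threshold_fraction": 0.1},
        "histogram": {"bin_width_nS": 0.25, "threshold": 0.15, "smooth_window": 3},
        "calibration": {"hille": {"conductivity": 10.5, "length": 3.5}},
        "bootstrap": {"B": 8192},
    }


def _config_hash(cfg: dict) -> str:
    blob = yaml.safe_dump(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(config: dict, output_dir) -> dict:
    """Execute every stage of the analysis and write the result bundle."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    seeds = _spawn_seeds(seed, 4)
    bundle: dict = {"config_hash": _config_hash(config), "version": __version__, "seed": seed}

    sim = config.get("simulate", default_config()["simulate"])
    det = config.get("detection", default_config()["detection"])
    hist_cfg = config.get("histogram", default_config()["histogram"])
    cal_cfg = config.get("calibration", default_config()["calibration"])
    boot_cfg = config.get("bootstrap", default_config()["bootstrap"])

    try:
        # --- signal ensemble -> classification -> stable fraction -------
        weights = sim["class_weights"]
        labels = list(weights)
        probs = np.array([weights[k] for k in labels], dtype=float)
        probs = probs / probs.sum()
        rng = np.random.default_rng(seeds[0])
        noise_sd = float(sim["noise_sd_pA"])
        rows = []
        calls = []
        for i in range(int(sim["n_signals"])):
            label = labels[int(rng.choice(len(labels), p=probs))]
            morph = SignalMorphology(
                label=label, level_count=3 if label == "multi-level" else 1
            )
            trace, truth = simulate_insertion_signal(
                morph,
                unit_conductance_nS=float(sim["unit_conductance_nS"]),
                voltage_mV=float(sim["voltage_mV"]),
                noise_sd=noise_sd,
                seed=int(rng.integers(2**31)),
            )
            call = classify_trace(trace, noise_sd=noise_sd, min_dwell_ms=det["min_dwell_ms"])
            calls.append(call)
            rows.append(
                {"signal_id": i, "true_class": label, "class": call.label, "stability": call.stability}
            )
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "classification.csv", index=False)
        bundle["stable_fraction"] = stable_fraction(calls)

        # --- conductance sample -> peaks --------------------------------
        g = sample_conductances(
            DEFAULT_CONDUCTANCE_MIXTURE, n=int(sim["conductance_sample_n"]), seed=seeds[1]
        )
        peak_res = ConductancePeakModel(g, bin_width=hist_cfg["bin_width_nS"]).fit(
            threshold=hist_cfg["threshold"], smooth_window=hist_cfg["smooth_window"]
        )
        (out / "peaks.json").write_text(json.dumps(peak_res.to_dict(), indent=2))
        bundle["peaks"] = peak_res.to_dict()

        # --- calibration -> geometry per fitted peak ---------------------
        calib = PoreCalibration().fit()
        hille = HilleParams(**cal_cfg.get("hille", {}))
        geom = []
        for m in peak_res.components["mean_nS"]:
            gobj = calib.geometry(float(m))
            row = gobj.to_dict()
            row["hille_diameter_nm"] = hille_diameter(float(m), hille)
            geom.append(row)
        (out / "geometry.json").write_text(json.dumps(geom, indent=2))
        bundle["geometry"] = geom

        # --- event stream -> blockades -> bootstrap peak -----------------
        es = sim["event_stream"]
        trace, truth = simulate_event_stream(
            KineticsModel(),
            concentration_nM=float(es["concentration_nM"]),
            voltage_mV=float(es["voltage_mV"]),
            duration_s=float(es["duration_s"]),
            open_current_pA=float(es["open_current_pA"]),
            noise_sd=noise_sd,
            seed=seeds[2],
        )
        write_trace(trace, out / "event_stream.tsv", seed=seeds[2])
        events = detect_blockade_events(
            trace,
            open_level_pA=float(es["open_current_pA"]),
            threshold_fraction=det["threshold_fraction"],
            min_dwell_ms=det["min_dwell_ms"],
            noise_sd=noise_sd,
        )
        write_events(events, out / "events.csv")
        stats: dict = {
            "n_events": len(events),
            "event_frequency_per_s": event_frequency(events, float(es["duration_s"])),
        }
        if events:
            boot = exact_bootstrap_means(
                events, BootstrapConfig(B=int(boot_cfg["B"]), seed=seeds[3])
            )
            boot.to_frame().to_csv(out / "bootstrap_pairs.csv", index=False)
            d_pk, a_pk = scatter_peak(boot)
            stats["scatter_peak"] = {"duration_ms": d_pk, "amplitude_pA": a_pk}
            stats["signal_to_noise"] = signal_to_noise(events, noise_sd)
        (out / "stats.json").write_text(json.dumps(stats, indent=2))
        bundle["translocation"] = stats
    except Exception as exc:  # pragma: no cover - error path
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    save_config(
        {"config": config, "config_hash": bundle["config_hash"], "stage_seeds": seeds,
         "version": __version__},
        out / "run.yaml",
    )
    (out / "report.json").write_text(json.dumps(bundle, indent=2, default=float))
    return bundle
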