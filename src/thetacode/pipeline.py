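"""End-to-end orchestration: synth -> preprocess -> classify -> decode -> LFP.

`run_pipeline` drives a whole synthetic-session analysis from a single
config dict and writes every artifact plus a provenance manifest
(config hash, seeds, stage timings) into a run directory. The helpers
(`classify_session`, `decode_session`) are the re-usable building blocks.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as tio
from . import lfp as tlfp
from .decoding import bootstrap_decode
from .preprocess import SessionBehavior, binarize_traces
from .synth import (CellSpec, LfpPlan, TrackConfig, make_population,
                    simulate_lfp, simulate_neurons, simulate_track_session)
from .tuning import (circular_shuffle_test, classify_cells, default_binning,
                     stim_modulation)

__all__ = [
    "DEFAULT_CONFIG",
    "variable_series",
    "classify_session",
    "decode_session",
    "run_pipeline",
    "compare_sessions",
]

DEFAULT_CONFIG: Dict = {
    "seed": 0,
    "track": {},                     # TrackConfig overrides
    "population": {"n_place": 25, "n_time": 15, "n_distance": 10, "n_untuned": 10},
    "calcium": {"calcium_tau": 0.5, "noise_sd": 0.05},
    "n_shuffles": 1000,
    "alpha": 0.05,
    "decode": {"n_boot": 50, "cells_per_boot": 160, "window_s": 2.0},
    "lfp": {"duration": 120.0, "n_ripples": 10},
}


def variable_series(behavior: SessionBehavior) -> Dict[str, np.ndarray]:
    """The three decoded/classified variables of a track session."""
    return {
        "location": behavior.position,
        "time": behavior.elapsed_s,
        "distance": behavior.distance_cm,
    }


def _masked_bins(behavior: SessionBehavior, variable: str) -> np.ndarray:
    spec = default_binning(variable)
    idx = spec.bin(variable_series(behavior)[variable])
    return np.where(behavior.locomotion_mask, idx, -1)


def classify_session(
    behavior: SessionBehavior,
    binary: np.ndarray,
    n_shuffles: int = 1000,
    alpha: float = 0.05,
    seed: Optional[int] = None,
    variables: Sequence[str] = ("location", "time", "distance"),
) -> pd.DataFrame:
    """Per-cell MI, shuffle p-values and label for every variable.

    One row per cell with columns ``mi_<var>``, ``p_<var>`` and ``label``.
    A single generator seeds the whole table so re-running with the same
    seed reproduces it exactly.
    """
    rng = np.random.default_rng(seed)
    bins = {v: _masked_bins(behavior, v) for v in variables}
    n_bins = {v: default_binning(v).n_bins for v in variables}
    rows = []
    for c in range(binary.shape[0]):
        row: Dict[str, object] = {"cell": c}
        pvals = {}
        for v in variables:
            mi, p, _ = circular_shuffle_test(
                binary[c], bins[v], n_bins[v], n_shuffles=n_shuffles, rng=rng,
                min_shift_frames=int(behavior.frame_rate))
            row[f"mi_{v}"] = mi
            row[f"p_{v}"] = p
            pvals[v] = p
        row["label"] = classify_cells(pvals, alpha)
        rows.append(row)
    return pd.DataFrame(rows)


def classify_stim_modulation(
    behavior: SessionBehavior,
    binary: np.ndarray,
    n_shuffles: int = 1000,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Per-cell stimulation-modulation table (MI vs the stim state)."""
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(binary.shape[0]):
        r = stim_modulation(binary[c], behavior.stim_mask,
                            n_shuffles=n_shuffles, rng=rng)
        rows.append({"cell": c, "stim_mi": r["mi_bits"], "stim_p": r["p_value"],
                     "direction": r["direction"],
                     "modulated": r["p_value"] <= alpha})
    return pd.DataFrame(rows)


def decode_session(
    behavior: SessionBehavior,
    binary: np.ndarray,
    variables: Sequence[str] = ("location", "time", "distance"),
    n_boot: int = 50,
    cells_per_boot: int = 160,
    window_s: float = 2.0,
    seed: Optional[int] = None,
) -> Dict[str, Dict[str, object]]:
    """Bootstrap naive Bayes decoding of each variable; summary per variable."""
    rng = np.random.default_rng(seed)
    out: Dict[str, Dict[str, object]] = {}
    for v in variables:
        res = bootstrap_decode(
            binary, _masked_bins(behavior, v), default_binning(v),
            frame_rate=behavior.frame_rate, n_boot=n_boot,
            cells_per_boot=cells_per_boot, window_s=window_s,
            trial_id=behavior.trial_id,
            seed=int(rng.integers(0, 2**31 - 1)))
        out[v] = res
    return out


def _config_hash(config: Dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: Optional[Dict] = None, out_dir: str | Path = "run") -> Path:
    """Run the full synthetic pipeline and write artifacts + manifest."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    if config:
        for k, v in config.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    rng = np.random.default_rng(seed)
    manifest: Dict[str, object] = {"config": cfg, "config_hash": _config_hash(cfg),
                                   "seed": seed, "stages": {}}

    def stage(name):
        t0 = time.perf_counter()
        def done():
            manifest["stages"][name] = round(time.perf_counter() - t0, 3)
        return done

    # --- behavior + neurons ------------------------------------------------
    d = stage("synth")
    track = TrackConfig(**cfg["track"])
    behavior = simulate_track_session(track, seed=int(rng.integers(2**31 - 1)))
    specs = make_population(rng=rng, **cfg["population"])
    neural, truth = simulate_neurons(
        behavior, specs, seed=int(rng.integers(2**31 - 1)), **cfg["calcium"])
    d()

    d = stage("preprocess")
    binary = binarize_traces(neural.traces, behavior.frame_rate)
    tio.write_behavior(behavior, out / "behavior.csv")
    tio.write_traces(neural, out / "traces.tsv")
    d()

    d = stage("classify")
    table = classify_session(behavior, binary, n_shuffles=int(cfg["n_shuffles"]),
                             alpha=float(cfg["alpha"]),
                             seed=int(rng.integers(2**31 - 1)))
    table["true_class"] = [s.cell_class for s in specs]
    table.to_csv(out / "classification.csv", index=False)
    d()

    d = stage("decode")
    dec = decode_session(behavior, binary, seed=int(rng.integers(2**31 - 1)),
                         **{k: cfg["decode"][k] for k in ("n_boot", "cells_per_boot", "window_s")})
    summary = {v: {"mean_error": r["mean_error"],
                   "shuffled_mean_error": r["shuffled_mean_error"],
                   "z": r["z"]} for v, r in dec.items()}
    tio.write_json(summary, out / "decoding.json")
    d()

    d = stage("lfp")
    duration = float(cfg["lfp"]["duration"])
    rip_rng = np.random.default_rng(int(rng.integers(2**31 - 1)))
    ripple_times = np.sort(rip_rng.uniform(5, duration - 5, int(cfg["lfp"]["n_ripples"])))
    plan = LfpPlan(duration=duration, ripple_times=tuple(ripple_times))
    sig, lfp_truth = simulate_lfp(plan, seed=int(rng.integers(2**31 - 1)))
    rest = tlfp.quiet_rest_mask(sig.samples, sig.fs)
    events = tlfp.detect_ripples(sig.samples, sig.fs, rest_mask=None)
    metrics = {
        "oscillation_strength": tlfp.oscillation_strength(sig.samples[:int(5 * sig.fs)], sig.fs),
        "n_ripples_detected": len(events),
        "n_ripples_injected": len(ripple_times),
        "rest_fraction": float(rest.mean()),
    }
    tio.write_json(metrics, out / "lfp_metrics.json")
    pd.DataFrame([{"peak_time_s": e.peak_time, "peak_z": e.peak_z,
                   "width_s": e.width_s} for e in events]).to_csv(
        out / "ripples.csv", index=False)
    d()

    tio.write_json(manifest, out / "manifest.json")
    return out


def compare_sessions(
    curves_a: Dict[int, np.ndarray],
    curves_b: Dict[int, np.ndarray],
    cell_mapping: Iterable[Tuple[int, int]],
) -> pd.DataFrame:
    """Field stability of matched cell pairs across two sessions.

    ``cell_mapping`` pairs cell ids of session A with ids of session B
    (identity for synthetic data; an external registration table
    otherwise). Returns one row per pair with the tuning-curve Pearson
    correlation.
    """
    from .tuning import field_stability
    mapping = list(cell_mapping)
    if len(mapping) == 0:
        raise ValueError("empty cell mapping")
    rows = []
    for a, b in mapping:
        rows.append({"cell_a": a, "cell_b": b,
                     "stability": field_stability(curves_a[a], curves_b[b])})
    return pd.DataFrame(rows)
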