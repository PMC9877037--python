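"""File formats: tidy behavior tables, trace matrices, LFP, ground truth.

Behavior is one CSV row per frame; traces are a dense TSV matrix
(rows = cells) with a JSON sidecar for the frame rate and cell ids; LFP is
a two-column CSV (time_s, uv) or an HDF5 dataset; ground truth and result
summaries are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import h5py
import numpy as np
import pandas as pd

from .lfp import LFPSignal
from .preprocess import NeuralData, SessionBehavior

__all__ = [
    "write_behavior", "read_behavior",
    "write_traces", "read_traces",
    "write_lfp", "read_lfp",
    "write_json", "read_json",
]


def write_behavior(behavior: SessionBehavior, path: str | Path) -> Path:
    path = Path(path)
    behavior.to_frame().to_csv(path, index=False)
    meta = path.with_suffix(path.suffix + ".json")
    meta.write_text(json.dumps({"frame_rate": behavior.frame_rate}))
    return path


def read_behavior(path: str | Path, frame_rate: Optional[float] = None) -> SessionBehavior:
    path = Path(path)
    if frame_rate is None:
        meta = path.with_suffix(path.suffix + ".json")
        if meta.exists():
            frame_rate = json.loads(meta.read_text())["frame_rate"]
        else:
            df0 = pd.read_csv(path, usecols=["time_s"])
            frame_rate = 1.0 / float(np.median(np.diff(df0["time_s"])))
    return SessionBehavior.from_frame(pd.read_csv(path), frame_rate)


def write_traces(neural: NeuralData, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, neural.traces, delimiter="\t", fmt="%.5f")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "frame_rate": neural.frame_rate,
        "cell_ids": [int(c) for c in neural.cell_ids],
    }))
    return path


def read_traces(path: str | Path, binarizer=None) -> NeuralData:
    path = Path(path)
    traces = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text())
    if binarizer is None:
        from .preprocess import binarize_traces
        binarizer = binarize_traces
    binary = binarizer(traces, meta["frame_rate"])
    return NeuralData(traces=traces, binary=binary,
                      frame_rate=meta["frame_rate"],
                      cell_ids=np.asarray(meta.get("cell_ids")))


def write_lfp(sig: LFPSignal, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("lfp_uv", data=sig.samples)
            ds.attrs["fs"] = sig.fs
            ds.attrs["channel"] = sig.channel
            if sig.stim_epochs:
                f.create_dataset("stim_epochs", data=np.array(
                    [(s, e) for (s, e, _) in sig.stim_epochs]))
                f.create_dataset("stim_patterns", data=np.array(
                    [p for (_, _, p) in sig.stim_epochs], dtype="S16"))
    else:
        pd.DataFrame({"time_s": sig.time_s, "uv": sig.samples}).to_csv(path, index=False)
        meta = {"fs": sig.fs, "channel": sig.channel,
                "stim_epochs": [list(e) for e in sig.stim_epochs]}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))
    return path


def read_lfp(path: str | Path) -> LFPSignal:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            ds = f["lfp_uv"]
            samples = ds[:]
            fs = float(ds.attrs["fs"])
            channel = str(ds.attrs.get("channel", "ch0"))
            epochs = []
            if "stim_epochs" in f:
                spans = f["stim_epochs"][:]
                pats = [p.decode() for p in f["stim_patterns"][:]]
                epochs = [(float(s), float(e), p) for (s, e), p in zip(spans, pats)]
        return LFPSignal(samples=samples, fs=fs, stim_epochs=epochs, channel=channel)
    df = pd.read_csv(path)
    meta_path = path.with_suffix(path.suffix + ".json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        fs = float(meta["fs"])
        epochs = [tuple(e) for e in meta.get("stim_epochs", [])]
        channel = meta.get("channel", "ch0")
    else:
        fs = 1.0 / float(np.median(np.diff(df["time_s"])))
        epochs, channel = [], "ch0"
    return LFPSignal(samples=df["uv"].to_numpy(float), fs=fs,
                     stim_epochs=epochs, channel=channel)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder))
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
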