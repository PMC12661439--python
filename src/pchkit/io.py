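"""Readers and writers for traces, histograms, fits and result tables.

Traces travel as two-column CSV (bin_index, count) with a JSON sidecar
(``<name>.json``) holding the sampling frequency and any metadata; histograms
as (k, frequency) CSV with the sampling frequency in a comment header; fit
and calibration results as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .pch import PCHFit, SpeciesComponent
from .trace import PCHistogram, PhotonCountTrace

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_histogram_csv",
    "read_histogram_csv",
    "write_fit_json",
    "read_fit_json",
    "write_json",
    "read_json",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trace_csv(trace: PhotonCountTrace, path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {"bin_index": np.arange(len(trace)), "count": trace.counts.astype(np.int64)}
    )
    df.to_csv(path, index=False)
    meta = {"sampling_frequency": trace.sampling_frequency, **trace.metadata}
    _sidecar(path).write_text(json.dumps(_jsonable(meta), indent=1))


def read_trace_csv(path) -> PhotonCountTrace:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    f_s = meta.pop("sampling_frequency")
    return PhotonCountTrace(df["count"].to_numpy(np.int64), f_s, meta)


def write_histogram_csv(histogram: PCHistogram, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sampling_frequency_hz={histogram.sampling_frequency!r}\n")
        fh.write("k,frequency\n")
        for k, f in zip(histogram.counts_axis, histogram.frequency):
            fh.write(f"{k},{f}\n")


def read_histogram_csv(path) -> PCHistogram:
    path = Path(path)
    f_s = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# sampling_frequency_hz="):
            f_s = float(first.split("=", 1)[1])
    if f_s is None:
        raise ValueError("histogram CSV is missing its sampling-frequency header")
    df = pd.read_csv(path, comment="#")
    freq = np.zeros(int(df["k"].max()) + 1, dtype=np.int64)
    freq[df["k"].to_numpy(int)] = df["frequency"].to_numpy(np.int64)
    return PCHistogram(freq, f_s)


def _jsonable(obj: Any):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def write_json(obj: Any, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1))


def read_json(path) -> Any:
    return json.loads(Path(path).read_text())


def write_fit_json(fit: PCHFit, path) -> None:
    payload = {
        "brightness_cpsm": fit.brightness,
        "number": fit.number,
        "species": [
            {"brightness_cpsm": s.brightness, "mean_number": s.mean_number}
            for s in fit.species
        ],
        "reduced_chi_square": fit.reduced_chi_square,
        "k_max_used": fit.k_max_used,
        "n_pooled_bins": fit.n_pooled_bins,
        "converged": fit.converged,
        "message": fit.message,
        "sampling_frequency": fit.sampling_frequency,
    }
    write_json(payload, path)


def read_fit_json(path) -> PCHFit:
    d = read_json(path)
    return PCHFit(
        species=[
            SpeciesComponent(s["brightness_cpsm"], s["mean_number"])
            for s in d["species"]
        ],
        reduced_chi_square=d["reduced_chi_square"],
        k_max_used=d["k_max_used"],
        converged=d["converged"],
        n_pooled_bins=d["n_pooled_bins"],
        message=d.get("message", ""),
        sampling_frequency=d.get("sampling_frequency", 0.0),
    )
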