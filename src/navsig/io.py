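"""Delimited trace tables, results tables and structured configs.

The interchange format for current traces is a UTF-8 tab-separated
table: one ``time_ms`` column plus one current column (pA) per sweep,
header row naming the condition of each column, '.' decimal.  A YAML
sidecar (``<table>.meta.yaml``) carries the sampling interval, the
test-onset time, truncation window and provenance, so a write-read
round trip is lossless to full floating precision.

Model and protocol configurations are YAML mappings mirroring the
constructors in :mod:`navsig.schemes` and :mod:`navsig.protocols`;
unknown keys are rejected rather than silently defaulted.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .acquisition import PatchDataset
from .schemes import ChannelModel, model_from_dict, model_to_dict
from .simulate import CurrentTrace

__all__ = [
    "write_trace_table", "read_trace_table",
    "write_results_table", "read_results_table",
    "save_model", "load_model",
    "save_dataset", "load_dataset",
]

_FLOAT_FMT = "%.17g"


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".meta.yaml")


def write_trace_table(traces, path) -> None:
    """Write one or more traces sharing a time base to a TSV + sidecar."""
    if isinstance(traces, CurrentTrace):
        traces = [traces]
    traces = list(traces)
    if not traces:
        raise ValueError("no traces to write")
    dt = traces[0].dt
    n = traces[0].n_samples
    onset = traces[0].onset_index
    for tr in traces[1:]:
        if tr.dt != dt or tr.n_samples != n or tr.onset_index != onset:
            raise ValueError("all traces in one table must share dt, length "
                             "and onset")
    names = []
    cols = {"time_ms": traces[0].time}
    for k, tr in enumerate(traces):
        if tr.condition_voltage is not None:
            name = f"I_{tr.condition_voltage:+.1f}mV"
        elif tr.protocol is not None and tr.protocol.label:
            name = f"I_{tr.protocol.label}"
        else:
            name = f"I_{k}"
        if name in cols:  # disambiguate duplicates
            name = f"{name}_{k}"
        names.append(name)
        cols[name] = tr.current
    df = pd.DataFrame(cols)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)

    meta = {
        "sampling_interval_ms": float(dt),
        "onset_index": int(onset),
        "n_samples": int(n),
        "columns": [
            {"name": name,
             "condition_voltage": (None if tr.condition_voltage is None
                                   else float(tr.condition_voltage)),
             "meta": {k: v for k, v in tr.meta.items()
                      if isinstance(v, (str, int, float, bool, type(None)))}}
            for name, tr in zip(names, traces)
        ],
        "truncate_after_onset_ms": _truncation_of(traces[0]),
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def _truncation_of(trace: CurrentTrace) -> float:
    if trace.excluded is None or not trace.excluded.any():
        return 0.0
    idx = np.flatnonzero(trace.excluded)
    return float((idx.max() - trace.onset_index + 1) * trace.dt)


def read_trace_table(path) -> list[CurrentTrace]:
    """Read a trace table written by :func:`write_trace_table`.

    A malformed header or non-uniform time base is rejected with the
    offending line number.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.shape[1] < 2 or df.columns[0] != "time_ms":
        raise ValueError(f"{path}: line 1: expected a 'time_ms' column followed "
                         "by current columns")
    t = df["time_ms"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    steps = np.diff(t)
    if np.any(steps <= 0):
        k = int(np.argmax(steps <= 0))
        raise ValueError(f"{path}: line {k + 3}: time column not strictly "
                         "increasing")
    dt = steps.mean()
    if np.any(np.abs(steps - dt) > 1e-9 * max(abs(dt), 1.0)):
        k = int(np.argmax(np.abs(steps - dt) > 1e-9 * max(abs(dt), 1.0)))
        raise ValueError(f"{path}: line {k + 3}: non-uniform time base")

    sidecar = _sidecar_path(path)
    meta = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
        dt = float(meta.get("sampling_interval_ms", dt))
    onset = int(meta.get("onset_index", 0))
    trunc = float(meta.get("truncate_after_onset_ms", 0.0))
    col_meta = {c["name"]: c for c in meta.get("columns", [])}

    traces = []
    for name in df.columns[1:]:
        y = df[name].to_numpy(dtype=float)
        excluded = None
        if trunc > 0:
            t_rel = (np.arange(y.size) - onset) * dt
            excluded = (t_rel >= -1e-12) & (t_rel < trunc - 1e-12)
        cm = col_meta.get(name, {})
        traces.append(CurrentTrace(
            dt=dt, current=y, onset_index=onset, protocol=None,
            condition_voltage=cm.get("condition_voltage"),
            excluded=excluded, meta=dict(cm.get("meta", {}))))
    return traces


def write_results_table(df: pd.DataFrame, path) -> None:
    """Write a fit-results table as TSV at full floating precision."""
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def save_model(model: ChannelModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_model(path) -> ChannelModel:
    """Load a channel-model config (also the hook for hand-translated
    literature Markov schemes expressed in the same YAML format)."""
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# dataset persistence (one table per patch + a manifest)


def save_dataset(dataset: PatchDataset, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, patch in enumerate(dataset.traces):
        write_trace_table(patch, directory / f"patch_{i:02d}.tsv")
    manifest = {
        "mode": dataset.mode,
        "n_patches": dataset.n_patches,
        "scales": [float(s) for s in dataset.scales],
        "meta": _plain(dataset.meta),
    }
    with open(directory / "dataset.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def _plain(obj):
    """Recursively coerce metadata to plain YAML-safe scalars."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()
                if isinstance(v, (str, int, float, bool, dict, list,
                                  np.integer, np.floating, type(None)))}
    if isinstance(obj, list):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return obj


def load_dataset(directory) -> PatchDataset:
    directory = Path(directory)
    with open(directory / "dataset.yaml") as fh:
        manifest = yaml.safe_load(fh)
    patches = []
    for i in range(int(manifest["n_patches"])):
        patches.append(read_trace_table(directory / f"patch_{i:02d}.tsv"))
    return PatchDataset(traces=patches, scales=np.array(manifest["scales"]),
                        mode=manifest["mode"], meta=manifest.get("meta", {}))
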