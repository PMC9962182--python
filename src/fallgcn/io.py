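"""CSV ingestion/export, run configuration and reproducibility manifests.

Trial data travel as plain per-frame CSV: a timestamp column, 30 channel
columns (5 sensors x 6 axes) and a label column, plus subject/activity/trial
metadata columns. The exact column names live in a YAML mapping file (a
default ships with the package) so a differently-dialected export — e.g.
the consolidated UP-Fall download — can be ingested by editing the mapping
rather than the code. The synthetic generator writes the same layout, so
the synthetic and real paths share every downstream step.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .windowing import SensorSequence

__all__ = [
    "load_column_map",
    "write_trial_csv",
    "write_dataset_csv",
    "read_sensor_csv",
    "read_upfall_csv",
    "RunConfig",
    "write_manifest",
]

log = logging.getLogger("fallgcn")


def load_column_map(path=None) -> dict:
    """Column-mapping dict (the packaged default when no path is given)."""
    if path is None:
        text = (
            resources.files("fallgcn.data").joinpath("upfall_columns.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if "sensors" not in doc or len(doc["sensors"]) < 1:
        raise ValueError("column map must list at least one sensor")
    for s in doc["sensors"]:
        if len(s["columns"]) != 6:
            raise ValueError(f"sensor {s.get('node')} must list exactly 6 columns")
    return doc


def _channel_columns(cmap: dict) -> list[str]:
    return [c for s in cmap["sensors"] for c in s["columns"]]


def write_trial_csv(seq: SensorSequence, path, cmap: dict | None = None) -> None:
    """One row per frame: timestamp, metadata, 30 channels, label."""
    cmap = cmap or load_column_map()
    frames, nodes, _ = seq.values.shape
    if nodes != len(cmap["sensors"]):
        raise ValueError("sequence node count does not match column map")
    data = {cmap["time_column"]: np.arange(frames) / seq.rate_hz}
    for key in ("subject", "activity", "trial"):
        col = cmap.get(f"{key}_column")
        if col:
            data[col] = seq.trial_meta.get(key, 0)
    flat = seq.values.reshape(frames, nodes * 6)
    for i, col in enumerate(_channel_columns(cmap)):
        data[col] = flat[:, i]
    data[cmap["label_column"]] = seq.frame_labels
    pd.DataFrame(data).to_csv(path, index=False)


def write_dataset_csv(sequences, outdir, cmap: dict | None = None) -> list[str]:
    """One CSV per trial under ``outdir``; returns the written file names."""
    cmap = cmap or load_column_map()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = []
    for seq in sequences:
        m = seq.trial_meta
        name = (
            f"subject{m.get('subject', 0):02d}_activity{m.get('activity', 0):02d}"
            f"_trial{m.get('trial', 0):02d}.csv"
        )
        write_trial_csv(seq, outdir / name, cmap)
        names.append(name)
    return names


def _frame_to_sequence(df: pd.DataFrame, cmap: dict, meta: dict) -> SensorSequence:
    chan_cols = _channel_columns(cmap)
    n_before = len(df)
    df = df.dropna(subset=chan_cols)
    dropped = n_before - len(df)
    if dropped:
        log.warning("dropped %d row(s) with missing channel values", dropped)
    if len(df) == 0:
        raise ValueError("no complete rows left after dropping missing values")
    ts = df[cmap["time_column"]].to_numpy(dtype=float)
    if len(ts) > 1:
        dt = np.median(np.diff(ts))
        rate = 1.0 / dt if dt > 0 else 18.0
    else:
        rate = 18.0
    values = df[chan_cols].to_numpy(dtype=np.float32).reshape(len(df), -1, 6)
    labels = df[cmap["label_column"]].to_numpy(dtype=np.int64)
    return SensorSequence(values, labels, rate_hz=float(rate), trial_meta=meta)


def read_sensor_csv(path, cmap: dict | None = None) -> list[SensorSequence]:
    """Read one CSV file into one sequence per (subject, activity, trial).

    Files without metadata columns yield a single sequence. Rows with
    missing channel values are dropped (count logged); missing required
    columns raise an error naming them.
    """
    cmap = cmap or load_column_map()
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"{path}: empty file")
    required = [cmap["time_column"], cmap["label_column"], *_channel_columns(cmap)]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    group_cols = [
        cmap[k]
        for k in ("subject_column", "activity_column", "trial_column")
        if cmap.get(k) and cmap[k] in df.columns
    ]
    if not group_cols:
        return [_frame_to_sequence(df, cmap, {"source": str(path)})]
    out = []
    for key, sub in df.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        meta = {
            name: int(v)
            for name, v in zip(("subject", "activity", "trial"), key)
        }
        meta["source"] = str(path)
        out.append(_frame_to_sequence(sub, cmap, meta))
    return out


def read_upfall_csv(path, cmap: dict | None = None) -> list[SensorSequence]:
    """Read a CSV file or a directory of CSV files into sensor sequences."""
    path = Path(path)
    cmap = cmap or load_column_map()
    if path.is_dir():
        files = sorted(path.glob("*.csv"))
        if not files:
            raise ValueError(f"no CSV files found under {path}")
        out = []
        for f in files:
            out.extend(read_sensor_csv(f, cmap))
        return out
    return read_sensor_csv(path, cmap)


@dataclass
class RunConfig:
    """Everything a pipeline run needs, loadable from one YAML file."""

    graph_file: str | None = None
    strategy: str = "spatial-configuration"
    max_distance: int = 1
    window_sec: float = 2.0
    overlap_frac: float = 0.5
    minibatch_size: int = 128
    learning_rate: float = 1e-4
    max_epochs: int = 1000
    patience: int = 50
    train_frac: float = 0.8
    val_frac: float = 0.1
    test_frac: float = 0.1
    subjects: int = 17
    trials: int = 3
    rate_hz: float = 18.0
    noise_sd_accel: float = 0.05
    noise_sd_gyro: float = 5.0
    separability: float = 1.0
    seed: int = 0
    dataset_path: str | None = None
    output_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        return asdict(self)


def write_manifest(outdir, config: dict, seed: int, extra: dict | None = None) -> Path:
    """Record config hash, seed and package version for reproducibility."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    canonical = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "package_version": __version__,
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
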