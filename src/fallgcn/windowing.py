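"""Sliding-window segmentation of labelled multichannel IMU streams.

A :class:`SensorSequence` is one recorded trial: frames x nodes x 6 channels
(3-axis accelerometer in g, 3-axis gyroscope in deg/s) with one activity
label per frame. Segmentation cuts fixed-length windows (1, 2 or 3 s by
convention) with 50% overlap, assigns one label per window by majority
vote, and stacks everything into the samples x channels x frames x nodes
tensor the classifier consumes. Windows never straddle trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import h5py
import numpy as np

__all__ = [
    "BACKGROUND_LABEL",
    "SensorSequence",
    "WindowedDataset",
    "ChannelStats",
    "frames_per_window",
    "assign_label",
    "segment",
    "segment_many",
    "channel_stats",
    "normalize_channels",
]

#: label id reserved for frames/windows that belong to no annotated activity
BACKGROUND_LABEL = 0


@dataclass
class SensorSequence:
    """One trial of synchronized multi-IMU data with per-frame labels."""

    values: np.ndarray  # (frames, nodes, channels=6)
    frame_labels: np.ndarray  # (frames,) integer activity ids
    rate_hz: float = 18.0
    trial_meta: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.frame_labels = np.asarray(self.frame_labels, dtype=np.int64)
        if self.values.ndim != 3:
            raise ValueError("values must be (frames, nodes, channels)")
        if self.values.shape[0] < 1:
            raise ValueError("sequence must contain at least one frame")
        if self.values.shape[2] != 6:
            raise ValueError("expected 6 channels per node (3 accel + 3 gyro)")
        if self.frame_labels.shape != (self.values.shape[0],):
            raise ValueError("frame_labels length must equal frame count")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


@dataclass
class WindowedDataset:
    """Stacked windows: tensor (samples, channels, frames, nodes) + one label each."""

    tensor: np.ndarray
    labels: np.ndarray
    window_sec: float
    overlap_frac: float
    rate_hz: float

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.tensor.ndim != 4:
            raise ValueError("tensor must be (samples, channels, frames, nodes)")
        if len(self.labels) != self.tensor.shape[0]:
            raise ValueError("one label per window required")

    @property
    def n_samples(self) -> int:
        return self.tensor.shape[0]

    @property
    def frames_per_window(self) -> int:
        return self.tensor.shape[2]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("tensor", data=self.tensor, compression="gzip")
            f.create_dataset("labels", data=self.labels)
            f.attrs["window_sec"] = self.window_sec
            f.attrs["overlap_frac"] = self.overlap_frac
            f.attrs["rate_hz"] = self.rate_hz

    @classmethod
    def load(cls, path) -> "WindowedDataset":
        with h5py.File(path, "r") as f:
            return cls(
                tensor=f["tensor"][...],
                labels=f["labels"][...],
                window_sec=float(f.attrs["window_sec"]),
                overlap_frac=float(f.attrs["overlap_frac"]),
                rate_hz=float(f.attrs["rate_hz"]),
            )


def frames_per_window(window_sec: float, rate_hz: float) -> int:
    """Window length in frames: round(window_sec * rate_hz), at least 1."""
    if window_sec <= 0 or rate_hz <= 0:
        raise ValueError("window_sec and rate_hz must be positive")
    return max(1, round(window_sec * rate_hz))


def assign_label(
    frame_labels: np.ndarray,
    min_fraction: float = 0.5,
    background: int = BACKGROUND_LABEL,
) -> int:
    """Majority label of a window.

    Ties break in favour of the label whose first occurrence in the window is
    earliest. If the winning label covers less than ``min_fraction`` of the
    window it is replaced by the background id.
    """
    frame_labels = np.asarray(frame_labels)
    if frame_labels.size == 0:
        raise ValueError("empty label slice")
    uniq, first_pos, counts = np.unique(
        frame_labels, return_index=True, return_counts=True
    )
    best = np.lexsort((first_pos, -counts))[0]  # max count, then earliest
    if counts[best] / frame_labels.size < min_fraction:
        return background
    return int(uniq[best])


def _stride(w: int, overlap_frac: float) -> int:
    return max(1, round(w * (1.0 - overlap_frac)))


def segment(
    sequence: SensorSequence,
    window_sec: float,
    overlap_frac: float = 0.5,
    min_fraction: float = 0.5,
) -> WindowedDataset:
    """Cut one trial into overlapping fixed-length windows.

    Window count follows floor((frames - W) / stride) + 1 with
    stride = max(1, round(W * (1 - overlap_frac))); trailing frames that do
    not fill a window are dropped. A trial shorter than one window yields an
    empty dataset with a warning rather than an error, so heterogeneous trial
    lengths survive batch processing.
    """
    w = frames_per_window(window_sec, sequence.rate_hz)
    stride = _stride(w, overlap_frac)
    frames = sequence.n_frames
    if frames < w:
        warnings.warn(
            f"trial with {frames} frames is shorter than one {w}-frame window; "
            "producing no windows",
            stacklevel=2,
        )
        tensor = np.zeros((0, 6, w, sequence.n_nodes), dtype=np.float32)
        return WindowedDataset(tensor, np.zeros(0, np.int64), window_sec, overlap_frac, sequence.rate_hz)
    count = (frames - w) // stride + 1
    starts = np.arange(count) * stride
    # (frames, nodes, channels) -> per window (channels, frames, nodes)
    tensor = np.empty((count, 6, w, sequence.n_nodes), dtype=np.float32)
    labels = np.empty(count, dtype=np.int64)
    for k, s in enumerate(starts):
        win = sequence.values[s : s + w]  # (w, nodes, 6)
        tensor[k] = win.transpose(2, 0, 1)
        labels[k] = assign_label(sequence.frame_labels[s : s + w], min_fraction)
    return WindowedDataset(tensor, labels, window_sec, overlap_frac, sequence.rate_hz)


def segment_many(
    sequences: Sequence[SensorSequence],
    window_sec: float,
    overlap_frac: float = 0.5,
    min_fraction: float = 0.5,
    drop_background: bool = False,
) -> WindowedDataset:
    """Segment each trial independently and concatenate the windows."""
    if not sequences:
        raise ValueError("no sequences to segment")
    parts = [
        segment(s, window_sec, overlap_frac, min_fraction) for s in sequences
    ]
    tensor = np.concatenate([p.tensor for p in parts], axis=0)
    labels = np.concatenate([p.labels for p in parts], axis=0)
    if drop_background:
        keep = labels != BACKGROUND_LABEL
        tensor, labels = tensor[keep], labels[keep]
    rate = sequences[0].rate_hz
    return WindowedDataset(tensor, labels, window_sec, overlap_frac, rate)


@dataclass
class ChannelStats:
    """Per-channel mean/sd computed on the training split only."""

    mean: np.ndarray  # (channels,)
    sd: np.ndarray  # (channels,)


def channel_stats(dataset: WindowedDataset, indices: np.ndarray) -> ChannelStats:
    """z-scoring statistics over the given (training) sample indices.

    Statistics are pooled over samples, frames and nodes, one value per
    channel, so normalization is invariant to node relabelling. Channels
    with zero variance get sd clamped to 1.
    """
    sub = dataset.tensor[np.asarray(indices)]
    mean = sub.mean(axis=(0, 2, 3), dtype=np.float64)
    sd = sub.std(axis=(0, 2, 3), dtype=np.float64)
    sd = np.where(sd > 0, sd, 1.0)
    return ChannelStats(mean=mean, sd=sd)


def normalize_channels(dataset: WindowedDataset, stats: ChannelStats) -> WindowedDataset:
    """Apply training-split z-scoring to every sample (no leakage by design)."""
    mean = stats.mean.astype(np.float32)[None, :, None, None]
    sd = stats.sd.astype(np.float32)[None, :, None, None]
    return WindowedDataset(
        (dataset.tensor - mean) / sd,
        dataset.labels.copy(),
        dataset.window_sec,
        dataset.overlap_frac,
        dataset.rate_hz,
    )
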