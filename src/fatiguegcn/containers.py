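"""In-memory containers shared across the pipeline.

An :class:`EEGRecording` is a channels x samples matrix in microvolts with
10-20 channel labels; a :class:`WindowedDataset` is a labeled stack of
fixed-length windows with per-window provenance, which is what the GAN,
the graph builder and the classifier all consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np

__all__ = ["EEGRecording", "Window", "WindowedDataset"]


@dataclass
class EEGRecording:
    """Continuous multi-channel EEG, sample axis indexed half-open [start, end)."""

    data: np.ndarray  # (n_channels, n_samples), microvolts
    channel_labels: Sequence[str]
    fs: float
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Window:
    """One fixed-length analysis window (channels x window_length)."""

    data: np.ndarray
    label: int | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("window data must be 2-D (channels x samples)")
        if not np.isfinite(self.data).all():
            raise ValueError("window contains NaN/Inf")


class WindowedDataset:
    """A stack of labeled windows: X (n, channels, samples), y (n,) int labels.

    ``ids`` are stable window identifiers (used for order-insensitive splits
    and leakage guards); ``provenance`` carries origin metadata, including the
    ``is_augmented`` flag set by GAN augmentation.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        ids: Sequence[str] | None = None,
        provenance: Sequence[dict[str, Any]] | None = None,
    ) -> None:
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        if self.X.ndim != 3:
            raise ValueError("X must be (n_windows, n_channels, n_samples)")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y must have one label per window")
        n = self.X.shape[0]
        self.ids = list(ids) if ids is not None else [f"w{i:06d}" for i in range(n)]
        if len(self.ids) != n:
            raise ValueError("one id per window required")
        if len(set(self.ids)) != n:
            raise ValueError("window ids must be unique")
        self.provenance = (
            [dict(p) for p in provenance] if provenance is not None else [{} for _ in range(n)]
        )
        if len(self.provenance) != n:
            raise ValueError("one provenance record per window required")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    @property
    def n_samples(self) -> int:
        return self.X.shape[2]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)

    def label_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.y, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    def subset(self, indices: Iterable[int]) -> "WindowedDataset":
        idx = np.asarray(list(indices), dtype=int)
        return WindowedDataset(
            self.X[idx],
            self.y[idx],
            [self.ids[i] for i in idx],
            [self.provenance[i] for i in idx],
        )

    def class_subset(self, class_ids: Sequence[int], relabel: bool = False) -> "WindowedDataset":
        """Windows whose label is in ``class_ids``; optionally remap labels to 0..K-1
        following the order of ``class_ids``."""
        keep = [i for i, lab in enumerate(self.y) if lab in set(class_ids)]
        ds = self.subset(keep)
        if relabel:
            mapping = {c: i for i, c in enumerate(class_ids)}
            ds = WindowedDataset(
                ds.X,
                np.array([mapping[int(v)] for v in ds.y], dtype=int),
                ds.ids,
                [dict(p, original_class=int(v)) for p, v in zip(ds.provenance, ds.y)],
            )
        return ds

    @staticmethod
    def concat(parts: Sequence["WindowedDataset"]) -> "WindowedDataset":
        if not parts:
            raise ValueError("nothing to concatenate")
        return WindowedDataset(
            np.concatenate([p.X for p in parts], axis=0),
            np.concatenate([p.y for p in parts], axis=0),
            [i for p in parts for i in p.ids],
            [q for p in parts for q in p.provenance],
        )

    @staticmethod
    def from_windows(windows: Sequence[Window], ids: Sequence[str] | None = None) -> "WindowedDataset":
        if not windows:
            raise ValueError("empty window list")
        X = np.stack([w.data for w in windows])
        y = np.array([-1 if w.label is None else w.label for w in windows], dtype=int)
        return WindowedDataset(X, y, ids, [w.provenance for w in windows])
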