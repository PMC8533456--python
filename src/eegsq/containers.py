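"""In-memory containers shared across the pipeline stages.

``Recording`` holds a continuous multichannel signal with stimulus event
markers, ``EpochSet`` the stimulus-locked 1-s segments with class labels,
and ``FeatureMatrix`` the epochs x features table with one descriptor per
feature column.  All arrays are plain numpy; signals are in microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .montage import Montage

__all__ = ["Recording", "EpochSet", "FeatureMatrix", "FeatureDescriptor"]


@dataclass
class Recording:
    """Continuous multichannel EEG signal with event markers.

    Attributes
    ----------
    data
        channels x samples array, microvolts.
    rate
        Sampling rate in Hz.
    events
        List of ``(onset_sample, label)`` stimulus markers with strictly
        increasing onsets inside the data bounds.
    montage
        Electrode layout matching ``data``'s channel axis.
    """

    data: np.ndarray
    rate: float
    events: list[tuple[int, int]]
    montage: Montage | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be channels x samples")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        onsets = [int(on) for on, _ in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        if onsets and (onsets[0] < 0 or onsets[-1] >= self.data.shape[1]):
            raise ValueError("event onsets must lie within the data bounds")
        if self.montage is not None and self.montage.n_channels != self.data.shape[0]:
            raise ValueError("montage channel count does not match data")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass
class EpochSet:
    """Labeled fixed-length epochs cut from a recording.

    ``order`` is the chronological index of each epoch within the session
    (strictly increasing, preserved across rejection), ``block`` the index
    of the stimulus each epoch was cut from: epochs sharing a block are
    temporally contiguous and inherit one label.
    """

    data: np.ndarray  # epochs x channels x samples
    rate: float
    labels: np.ndarray  # per-epoch class label
    order: np.ndarray  # chronological epoch index
    block: np.ndarray  # stimulus index per epoch
    montage: Montage | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.order = np.asarray(self.order, dtype=int)
        self.block = np.asarray(self.block, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("EpochSet.data must be epochs x channels x samples")
        n = self.data.shape[0]
        if not (len(self.labels) == len(self.order) == len(self.block) == n):
            raise ValueError("labels/order/block must match the epoch count")
        if n and np.any(np.diff(self.order) <= 0):
            raise ValueError("order must be strictly increasing")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def subset(self, mask: np.ndarray) -> "EpochSet":
        """Row subset preserving original order indices."""
        return EpochSet(
            data=self.data[mask],
            rate=self.rate,
            labels=self.labels[mask],
            order=self.order[mask],
            block=self.block[mask],
            montage=self.montage,
        )


@dataclass(frozen=True)
class FeatureDescriptor:
    """Identity of one feature column: asymmetry mode, electrode pair, band, base."""

    mode: str  # DASM or RASM
    pair: tuple[str, str]
    band: str
    base: str  # PSD, Hjorth-activity, Hjorth-mobility, Hjorth-complexity, DE

    def __str__(self) -> str:
        return f"{self.mode}|{self.pair[0]}-{self.pair[1]}|{self.band}|{self.base}"


@dataclass
class FeatureMatrix:
    """Epochs x features table with per-column descriptors and row metadata."""

    values: np.ndarray
    descriptors: list[FeatureDescriptor]
    labels: np.ndarray
    order: np.ndarray
    block: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.order = np.asarray(self.order, dtype=int)
        self.block = np.asarray(self.block, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("FeatureMatrix.values must be 2-D")
        if self.values.shape[1] != len(self.descriptors):
            raise ValueError("descriptor count must match feature columns")
        if len({str(d) for d in self.descriptors}) != len(self.descriptors):
            raise ValueError("feature descriptors must be unique")
        n = self.values.shape[0]
        if not (len(self.labels) == len(self.order) == len(self.block) == n):
            raise ValueError("labels/order/block must match the row count")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "FeatureMatrix":
        """Same metadata, new value matrix of identical shape."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise ValueError("replacement values must keep the matrix shape")
        return replace(self, values=values)

    def select_columns(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            values=self.values[:, idx],
            descriptors=[self.descriptors[i] for i in idx],
            labels=self.labels,
            order=self.order,
            block=self.block,
        )

    def band_subset(self, bands: Sequence[str]) -> "FeatureMatrix":
        """Columns whose rhythm band is in ``bands``."""
        keep = [i for i, d in enumerate(self.descriptors) if d.band in bands]
        if not keep:
            raise ValueError(f"no features in bands {bands!r}")
        return self.select_columns(keep)
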