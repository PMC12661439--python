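"""Core data containers: binned photon-count traces and their histograms."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class PhotonCountTrace:
    """A time-ordered sequence of per-bin photon counts.

    Parameters
    ----------
    counts : ndarray of int
        Photon counts per sampling bin.
    sampling_frequency : float
        Bin rate f_s in Hz (20 kHz in a typical single-point FFS acquisition).
    metadata : dict
        Free-form acquisition / ground-truth annotations.
    """

    counts: np.ndarray
    sampling_frequency: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if self.sampling_frequency <= 0:
            raise ValueError("sampling_frequency must be positive")
        if np.any(self.counts < 0):
            raise ValueError("photon counts cannot be negative")

    def __len__(self) -> int:
        return self.counts.size

    @property
    def duration(self) -> float:
        """Total acquisition time in seconds."""
        return self.counts.size / self.sampling_frequency

    @property
    def mean_rate(self) -> float:
        """Mean detected intensity in counts/s."""
        return float(self.counts.mean()) * self.sampling_frequency

    def slice_seconds(self, start: float, stop: float) -> "PhotonCountTrace":
        i = int(round(start * self.sampling_frequency))
        j = int(round(stop * self.sampling_frequency))
        return PhotonCountTrace(
            self.counts[i:j], self.sampling_frequency, dict(self.metadata)
        )

    def to_histogram(self, k_max: int | None = None) -> "PCHistogram":
        return PCHistogram.from_trace(self, k_max=k_max)


@dataclass
class PCHistogram:
    """Frequency of sampling bins containing k photons, k = 0..k_max."""

    frequency: np.ndarray
    sampling_frequency: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequency = np.asarray(self.frequency, dtype=np.int64)
        if self.frequency.ndim != 1 or self.frequency.size == 0:
            raise ValueError("frequency must be a nonempty 1-D array")
        if np.any(self.frequency < 0):
            raise ValueError("frequencies cannot be negative")
        if self.sampling_frequency <= 0:
            raise ValueError("sampling_frequency must be positive")

    @property
    def counts_axis(self) -> np.ndarray:
        return np.arange(self.frequency.size)

    @property
    def k_max(self) -> int:
        return self.frequency.size - 1

    @property
    def total_bins(self) -> int:
        return int(self.frequency.sum())

    @property
    def mean(self) -> float:
        return float(self.counts_axis @ self.frequency) / self.total_bins

    @property
    def variance(self) -> float:
        """Population (denominator n) variance of the counts."""
        m = self.mean
        return float(((self.counts_axis - m) ** 2) @ self.frequency) / self.total_bins

    @classmethod
    def from_trace(
        cls, trace: PhotonCountTrace, k_max: int | None = None
    ) -> "PCHistogram":
        observed_max = int(trace.counts.max()) if len(trace) else 0
        if k_max is None:
            k_max = observed_max
        elif k_max < observed_max:
            raise ValueError("k_max is smaller than the largest observed count")
        freq = np.bincount(trace.counts.astype(np.int64), minlength=k_max + 1)
        return cls(freq, trace.sampling_frequency, dict(trace.metadata))
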