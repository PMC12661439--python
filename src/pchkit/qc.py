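"""Trace quality control: intensity-drift screening and segment selection.

Live-cell acquisitions can drift slowly (cell movement, focus); traces with
more than a 10 % fitted intensity change over their full length are not used
whole — instead analysis is restricted to the longest sub-segments (>= 10 s)
inside which the drift bound holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trace import PhotonCountTrace

__all__ = ["TraceQCReport", "qc_trace"]


@dataclass
class TraceQCReport:
    total_duration: float
    drift_fraction: float
    usable_segments: list[tuple[float, float]]
    passed: bool
    reason: str = ""


def _drift_fraction(t: np.ndarray, intensity: np.ndarray) -> float:
    """Fractional fitted intensity change over the window, from a linear fit."""
    if intensity.mean() == 0:
        return 0.0
    slope, _ = np.polyfit(t, intensity, 1)
    return float(slope * (t[-1] - t[0]) / intensity.mean())


def qc_trace(
    trace: PhotonCountTrace,
    max_drift: float = 0.10,
    min_segment: float = 10.0,
    coarse_bin: float = 1.0,
) -> TraceQCReport:
    """Screen a trace for slow intensity drift.

    The trace is rebinned to ``coarse_bin``-second intensities and a straight
    line fitted; if the fitted total change is within ``max_drift`` of the
    mean the whole trace is usable.  Otherwise the longest coarse-bin windows
    (each >= ``min_segment`` seconds) satisfying the bound are reported.
    Raises for traces shorter than ``min_segment``.
    """
    duration = trace.duration
    if duration < min_segment:
        raise ValueError(
            f"trace of {duration:.3g} s is shorter than the minimum usable "
            f"segment ({min_segment:.3g} s)"
        )
    per = int(round(coarse_bin * trace.sampling_frequency))
    n_coarse = len(trace) // per
    coarse = trace.counts[: n_coarse * per].reshape(n_coarse, per).sum(axis=1)
    t = (np.arange(n_coarse) + 0.5) * coarse_bin

    drift = _drift_fraction(t, coarse.astype(float))
    if abs(drift) <= max_drift:
        return TraceQCReport(duration, drift, [(0.0, duration)], True)

    min_bins = int(np.ceil(min_segment / coarse_bin))
    segments: list[tuple[float, float]] = []

    def longest_ok(lo: int, hi: int) -> tuple[int, int] | None:
        best = None
        for width in range(hi - lo, min_bins - 1, -1):
            for start in range(lo, hi - width + 1):
                window = slice(start, start + width)
                if abs(_drift_fraction(t[window], coarse[window].astype(float))) <= max_drift:
                    return (start, start + width)
        return best

    def collect(lo: int, hi: int) -> None:
        if hi - lo < min_bins:
            return
        found = longest_ok(lo, hi)
        if found is None:
            return
        a, b = found
        segments.append((a * coarse_bin, b * coarse_bin))
        collect(lo, a)
        collect(b, hi)

    collect(0, n_coarse)
    segments.sort()
    passed = bool(segments)
    return TraceQCReport(
        duration,
        drift,
        segments,
        passed,
        "" if passed else "no drift-free segment of sufficient length",
    )
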