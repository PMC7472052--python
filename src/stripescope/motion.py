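"""Trace-level analysis of recorded tissue motion.

Operates on the column-vs-time trace produced by stripe tracking:
peak-to-peak amplitude (robust to outliers via quantile trimming), dominant
frequency from the periodogram, conversion from image to world coordinates
through a calibration fit, and a JSON-ready summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy import signal

from .calibration import CalibrationFit, column_to_displacement

__all__ = [
    "MotionTrace",
    "FrequencyEstimate",
    "amplitude",
    "dominant_frequency",
    "convert_trace",
    "summarize",
]


@dataclass(frozen=True)
class MotionTrace:
    """Stripe-position time series; missing (invalid) frames are NaN columns."""

    times: np.ndarray
    columns: np.ndarray
    frame_rate: float = 30.0
    displacements: np.ndarray | None = None     # mm, set by convert_trace
    column_sd: np.ndarray | None = None
    n_rows_used: np.ndarray | None = None
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.columns, dtype=float)
        if t.ndim != 1 or t.shape != c.shape:
            raise ValueError("times and columns must be 1-D and the same length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "columns", c)
        if self.displacements is not None:
            d = np.asarray(self.displacements, dtype=float)
            if d.shape != t.shape:
                raise ValueError("displacements must match the trace length")
            object.__setattr__(self, "displacements", d)

    def __len__(self) -> int:
        return self.times.size

    @property
    def valid_fraction(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(np.mean(np.isfinite(self.columns)))

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self) > 1 else 0.0


class FrequencyEstimate(NamedTuple):
    frequency_hz: float
    resolution_hz: float


def _series(trace: MotionTrace, use: str) -> np.ndarray:
    if use == "displacements":
        if trace.displacements is None:
            raise ValueError("trace has no displacement values; run convert_trace first")
        return trace.displacements
    return trace.columns


def amplitude(trace: MotionTrace, robust_quantile: float = 0.01, use: str = "columns") -> float:
    """Peak-to-peak span of the trace.

    Computed as ``quantile(1 - q) - quantile(q)`` with ``q =
    robust_quantile`` so isolated tracking outliers do not inflate the
    span; ``q = 0`` gives the strict max - min.
    """
    if not 0.0 <= robust_quantile < 0.5:
        raise ValueError("robust_quantile must lie in [0, 0.5)")
    values = _series(trace, use)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("need at least 2 valid samples for an amplitude")
    return float(np.quantile(values, 1.0 - robust_quantile) - np.quantile(values, robust_quantile))


def dominant_frequency(trace: MotionTrace, use: str = "columns") -> FrequencyEstimate:
    """Frequency of the largest non-DC periodogram peak, with its bin width.

    Missing samples are linearly interpolated first (with a warning) so the
    periodogram sees a uniform series; the trace mean is subtracted and no
    window is applied (short physiological traces keep their full power in
    the main lobe that way).
    """
    values = np.array(_series(trace, use), dtype=float)
    finite = np.isfinite(values)
    if finite.sum() < 8:
        raise ValueError("need at least 8 valid samples for a frequency estimate")
    if not finite.all():
        warnings.warn("interpolating missing samples before the periodogram", stacklevel=2)
        values[~finite] = np.interp(
            trace.times[~finite], trace.times[finite], values[finite]
        )
    values = values - values.mean()
    if np.allclose(values, 0.0):
        raise ValueError("trace is constant: no spectral peak")
    freqs, power = signal.periodogram(values, fs=trace.frame_rate, window="boxcar")
    k = int(np.argmax(power[1:])) + 1  # skip the DC bin
    return FrequencyEstimate(
        frequency_hz=float(freqs[k]),
        resolution_hz=float(trace.frame_rate / values.size),
    )


def convert_trace(trace: MotionTrace, fit: CalibrationFit) -> MotionTrace:
    """Attach world-coordinate displacements (mm) via the calibration line."""
    disp = np.where(
        np.isfinite(trace.columns),
        column_to_displacement(fit, np.nan_to_num(trace.columns)),
        np.nan,
    )
    return replace(trace, displacements=disp)


def summarize(trace: MotionTrace, fit: CalibrationFit | None = None) -> dict:
    """JSON-ready motion report: sample counts, amplitudes, dominant frequency.

    A pure function of its inputs.  Amplitude in mm and the converted trace
    require a calibration fit; fields that cannot be computed are null.
    """
    report: dict = {
        "n_frames": len(trace),
        "valid_fraction": trace.valid_fraction,
        "duration_s": trace.duration_s,
        "frame_rate_hz": trace.frame_rate,
        "amplitude_px": None,
        "amplitude_mm": None,
        "dominant_freq_hz": None,
        "freq_resolution_hz": None,
    }
    n_valid = int(np.isfinite(trace.columns).sum())
    if n_valid >= 2:
        amp_px = amplitude(trace)
        report["amplitude_px"] = amp_px
        if fit is not None:
            report["amplitude_mm"] = amp_px / abs(fit.a)
    if n_valid >= 8:
        try:
            est = dominant_frequency(trace)
        except ValueError:
            pass
        else:
            report["dominant_freq_hz"] = est.frequency_hz
            report["freq_resolution_hz"] = est.resolution_hz
    return report
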