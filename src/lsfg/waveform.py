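"""Per-ROI MBR time series and pulse-waveform deviation metrics.

A recording's ROI series is the arithmetic mean of the in-ROI pixels of each
frame, in frame order.  Its pulsatile character is summarised by three
deviations around the series mean over the whole recording window:

* Max-Mean — peak minus mean,
* Mean-Min — mean minus trough,
* Max-Min  — peak minus trough, identically Max-Mean + Mean-Min.

No detrending, filtering or beat segmentation is applied.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import MBRFrameStack, ROI
from .errors import ValidationError


@dataclass(frozen=True)
class ROISeries:
    """One MBR value per frame (ROI mean), with the acquisition rate."""

    values: np.ndarray
    fps: float
    roi_name: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValidationError("series must be 1-D with length >= 1")
        if not np.isfinite(values).all():
            raise ValidationError("series contains non-finite values")
        if (values < 0).any():
            raise ValidationError("MBR series values must be non-negative")
        if self.fps <= 0:
            raise ValidationError(f"fps must be positive, got {self.fps}")
        object.__setattr__(self, "values", values)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.values.size) / self.fps


@dataclass(frozen=True)
class PulseMetrics:
    """Waveform deviations around the recording mean.

    ``max_min`` is stored as ``max_mean + mean_min`` so the additivity
    identity is exact in floating point; it equals max(series) - min(series)
    to within one ulp.
    """

    max_mean: float
    mean_min: float

    @property
    def max_min(self) -> float:
        return self.max_mean + self.mean_min


def roi_timeseries(stack: MBRFrameStack, roi: ROI) -> ROISeries:
    """Mean in-ROI MBR of every frame of a recording, in frame order."""
    h, w = stack.shape
    mask = roi.mask(h, w)
    if not mask.any():
        raise ValidationError(f"ROI {roi.name!r} covers no pixel centers")
    values = stack.frames[:, mask].mean(axis=1)
    return ROISeries(values=values, fps=stack.metadata.fps,
                     roi_name=roi.name)


def pulse_metrics(series: ROISeries) -> PulseMetrics:
    """Max-Mean, Mean-Min (and hence Max-Min) of a series."""
    v = series.values
    mean = float(v.mean())
    # clamp at 0: both deviations are non-negative by definition, but the
    # accumulated mean can overshoot max/min by an ulp on constant series
    return PulseMetrics(max_mean=max(0.0, float(v.max()) - mean),
                        mean_min=max(0.0, mean - float(v.min())))
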