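"""Signal-conditioning primitives shared by the systolic-peak detectors.

All stages are length-preserving so that sample indices remain valid
coordinates of the raw record throughout a detection pipeline. Filters are
zero-phase (forward-backward Butterworth), so event timing is not skewed by
filtering; moving averages are centered for the same reason.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Union

import numpy as np
from scipy import signal as sps

from .errors import ValidationError
from .signal_io import PPGRecord

Stage = Literal[
    "raw", "filtered", "clipped", "squared", "derivative", "ssf", "ma_peak", "ma_beat"
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter design: band edges in Hz, per-direction order.

    ``order`` is the design order of the underlying filter; zero-phase
    application runs it forward and backward, doubling the effective order
    while cancelling the phase response.
    """

    kind: Literal["bandpass", "lowpass"]
    high_hz: float
    low_hz: float | None = None
    order: int = 2
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if self.order < 1:
            raise ValidationError("filter order must be >= 1")
        if self.kind == "bandpass":
            if self.low_hz is None:
                raise ValidationError("bandpass filter needs a low corner")
            if not (0 < self.low_hz < self.high_hz < nyq):
                raise ValidationError(
                    f"bandpass corners must satisfy 0 < {self.low_hz} < "
                    f"{self.high_hz} < Nyquist ({nyq} Hz)"
                )
        elif self.kind == "lowpass":
            if not (0 < self.high_hz < nyq):
                raise ValidationError(
                    f"lowpass cutoff must satisfy 0 < {self.high_hz} < "
                    f"Nyquist ({nyq} Hz)"
                )
        else:  # pragma: no cover - dataclass Literal guards this
            raise ValidationError(f"unknown filter kind {self.kind!r}")


@dataclass(frozen=True)
class FeatureSignal:
    """A processed signal stage, index-aligned with its source record."""

    values: np.ndarray
    fs: float
    source_id: str = ""
    stage: Stage = "raw"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValidationError("feature signal must be 1-D with length >= 1")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.size)


SignalLike = Union[PPGRecord, FeatureSignal]


def as_feature(x: SignalLike, stage: Stage = "raw") -> FeatureSignal:
    if isinstance(x, FeatureSignal):
        return x
    return FeatureSignal(x.samples, x.fs, x.record_id, stage)


def ms_to_samples(ms: float, fs: float) -> int:
    """Convert milliseconds to samples, rounding half away from zero."""
    return int(math.floor(ms * fs / 1000.0 + 0.5))


def odd_window_samples(window_ms: float, fs: float) -> int:
    """Moving-average window length: nearest odd integer to ``window_ms``·fs.

    111 ms at 367 Hz gives 41 samples; 667 ms gives 245 samples. Exact
    half-odd ties round away from zero.
    """
    w = window_ms * fs / 1000.0
    return max(1, 2 * int(math.floor((w - 1.0) / 2.0 + 0.5)) + 1)


def butterworth_zero_phase(x: SignalLike, spec: FilterSpec) -> FeatureSignal:
    """Zero-phase Butterworth filter of a record or feature signal.

    The filter is realized as cascaded second-order sections and applied
    forward-backward (``sosfiltfilt``), which cancels phase lag and squares
    the magnitude response. A bandpass removes the DC component entirely.
    """
    src = as_feature(x)
    spec.validate(src.fs)
    if spec.kind == "bandpass":
        sos = sps.butter(
            spec.order, [spec.low_hz, spec.high_hz], btype="bandpass",
            fs=src.fs, output="sos",
        )
    else:
        sos = sps.butter(spec.order, spec.high_hz, btype="lowpass",
                         fs=src.fs, output="sos")
    if not spec.zero_phase:
        out = sps.sosfilt(sos, src.values)
    else:
        try:
            out = sps.sosfiltfilt(sos, src.values)
        except ValueError as exc:
            raise ValidationError(
                f"record of {len(src)} samples is shorter than the zero-phase "
                f"filter warm-up (edge padding) length; supply a longer record"
            ) from exc
    return FeatureSignal(out, src.fs, src.source_id, "filtered")


def clip_above_zero(x: SignalLike) -> FeatureSignal:
    """Half-wave rectification: ``out[n] = max(x[n], 0)``."""
    src = as_feature(x)
    return FeatureSignal(np.maximum(src.values, 0.0), src.fs, src.source_id, "clipped")


def square(x: SignalLike) -> FeatureSignal:
    """Pointwise square; emphasises the systolic upstroke over the diastolic
    wave and noise when applied after clipping."""
    src = as_feature(x)
    return FeatureSignal(src.values ** 2, src.fs, src.source_id, "squared")


def first_difference(x: SignalLike) -> FeatureSignal:
    """Backward first difference, ``out[0] = 0`` to preserve length."""
    src = as_feature(x)
    if len(src) < 2:
        raise ValidationError("first difference needs at least 2 samples")
    out = np.empty(len(src))
    out[0] = 0.0
    out[1:] = np.diff(src.values)
    return FeatureSignal(out, src.fs, src.source_id, "derivative")


def moving_average(x: SignalLike, window_ms: float, fs: float | None = None,
                   stage: Stage = "ma_peak") -> FeatureSignal:
    """Centered moving average with the nearest-odd window rule.

    The window ``W`` is the nearest odd number of samples to
    ``window_ms * fs / 1000``. At the record edges the window shrinks to the
    available samples (truncated mean, no padding), so the output length
    equals the input length.
    """
    src = as_feature(x)
    fs = src.fs if fs is None else fs
    if window_ms <= 0:
        raise ValidationError("moving-average window must be positive")
    w = odd_window_samples(window_ms, fs)
    n = len(src)
    if w > n:
        raise ValidationError(f"window of {w} samples exceeds signal length {n}")
    sums = np.convolve(src.values, np.ones(w), mode="same")
    counts = np.convolve(np.ones(n), np.ones(w), mode="same")
    return FeatureSignal(sums / counts, fs, src.source_id, stage)


def slope_sum(x: SignalLike, window_ms: float = 128.0,
              fs: float | None = None) -> FeatureSignal:
    """Slope sum function: windowed sum of positive first differences.

    ``SSF[n] = sum_{k=n-w+1..n} max(x[k] - x[k-1], 0)`` with
    ``w = round(window_ms * fs / 1000)`` (47 samples for 128 ms at 367 Hz).
    The first ``w`` samples sum over the available (truncated) history so the
    output stays index-aligned with the input. The SSF amplifies the pulse
    upslope and suppresses the rest of the waveform; it is invariant to
    adding a constant to the input.
    """
    src = as_feature(x)
    fs = src.fs if fs is None else fs
    w = ms_to_samples(window_ms, fs)
    if w < 1:
        raise ValidationError("slope-sum window must span at least 1 sample")
    n = len(src)
    if n <= w:
        raise ValidationError(f"signal length {n} must exceed SSF window {w}")
    up = np.zeros(n)
    up[1:] = np.maximum(np.diff(src.values), 0.0)
    csum = np.concatenate(([0.0], np.cumsum(up)))
    idx = np.arange(n)
    lo = np.maximum(0, idx - w + 1)
    out = csum[idx + 1] - csum[lo]
    return FeatureSignal(out, fs, src.source_id, "ssf")
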