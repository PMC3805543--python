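"""The four systolic-peak detectors.

Each detector maps a :class:`~ppgpeaks.signal_io.PPGRecord` to a
:class:`~ppgpeaks.signal_io.PeakAnnotation` of systolic-peak sample indices
in raw-record coordinates:

* :func:`detect_billauer` — alternating local maxima/minima with an absolute
  amplitude excursion threshold delta.
* :func:`detect_li` — first-derivative delineator with adaptive amplitude
  and interval thresholds initialized from short selective windows.
* :func:`detect_zong` — slope sum function with an adaptive threshold,
  onset search and refractory period.
* :func:`detect_elgendi` — two event-related moving averages (systolic-peak
  scale W1 and beat scale W2) over the squared, clipped, bandpassed signal;
  blocks of interest where the peak-scale average exceeds the beat-scale
  average plus an offset ``alpha = beta * mean(z)``; blocks narrower than W1
  samples are rejected as noise and each surviving block contributes the
  index of its maximum as a systolic peak.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ValidationError
from .preprocess import (
    FeatureSignal,
    FilterSpec,
    butterworth_zero_phase,
    clip_above_zero,
    first_difference,
    moving_average,
    ms_to_samples,
    odd_window_samples,
    slope_sum,
    square,
)
from .signal_io import PeakAnnotation, PPGRecord, annotation_from_indices


# ---------------------------------------------------------------------------
# parameter bundles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BillauerParams:
    """Local maxima/minima detector parameters.

    ``delta`` is an absolute amplitude excursion in the units of the
    processed signal (default 0.1): a running maximum becomes a peak once
    the signal drops more than ``delta`` below it. Because ``delta`` is
    absolute, the detector is *not* amplitude-scale invariant; set
    ``normalize`` to rescale the signal to unit maximum absolute amplitude
    first (the CLI does this), which makes ``delta = 0.1`` meaningful on
    arbitrary-unit recordings.
    """

    delta: float = 0.1
    use_bandpass: bool = True
    f1: float = 0.5
    f2: float = 8.0
    normalize: bool = False


@dataclass(frozen=True)
class LiParams:
    """First-derivative delineator parameters.

    The record is split into ``n_divisions`` equal divisions; a 2 s
    selective window at the start of each provides the initial amplitude and
    beat-interval estimates. ``amplitude_factor`` scales the running mean
    derivative-peak amplitude into the acceptance threshold; candidates
    closer than ``interval_factor_low`` times the running beat interval to
    the previous beat are rejected, and once a gap exceeds
    ``interval_factor_high`` times the running interval the amplitude
    threshold is relaxed (search-back) to half its value.
    """

    lowpass_hz: float = 8.0
    n_divisions: int = 3
    selective_window_s: float = 2.0
    amplitude_factor: float = 0.5
    interval_factor_low: float = 0.5
    interval_factor_high: float = 1.5


@dataclass(frozen=True)
class ZongParams:
    """Slope-sum detector parameters.

    The adaptive threshold base is initialized to three times the mean SSF
    over the first ``init_seconds``; the working threshold is
    ``threshold_fraction`` (60%) of the base, which is updated to each
    accepted pulse's SSF maximum. A threshold crossing is accepted when the
    SSF min/max excursion over the ``search_ms`` windows around it exceeds
    ``accept_min_excursion_fraction`` of the base. The pulse onset is the
    point where the SSF first exceeds ``onset_fraction`` (1%) of the pulse
    maximum, shifted earlier by ``phase_adjust_ms``; no new detection starts
    within ``refractory_ms`` of the previous one.
    """

    ssf_window_ms: float = 128.0
    init_seconds: float = 8.0
    threshold_fraction: float = 0.60
    search_ms: float = 150.0
    onset_fraction: float = 0.01
    phase_adjust_ms: float = 20.0
    refractory_ms: float = 300.0
    lowpass_hz: float = 16.0
    accept_min_excursion_fraction: float = 0.10

    def validate(self) -> None:
        for name in ("ssf_window_ms", "init_seconds", "search_ms",
                     "phase_adjust_ms", "refractory_ms", "lowpass_hz"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("threshold_fraction", "onset_fraction",
                     "accept_min_excursion_fraction"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")


@dataclass(frozen=True)
class ElgendiParams:
    """Event-related moving-average detector parameters.

    ``f1``-``f2`` is the bandpass (0.5-8 Hz default), ``w1_ms`` the
    systolic-peak moving-average window (111 ms), ``w2_ms`` the beat
    moving-average window (667 ms) and ``beta`` the dimensionless offset
    fraction (0.02) multiplying the mean of the squared clipped signal.
    """

    f1: float = 0.5
    f2: float = 8.0
    w1_ms: float = 111.0
    w2_ms: float = 667.0
    beta: float = 0.02

    def validate(self, fs: float) -> None:
        if not (0 < self.f1 < self.f2 < fs / 2):
            raise ValidationError(
                f"frequency band must satisfy 0 < f1 < f2 < fs/2; "
                f"got f1={self.f1}, f2={self.f2}, fs={fs}"
            )
        if not (0 < self.w1_ms < self.w2_ms):
            raise ValidationError(
                f"windows must satisfy 0 < W1 < W2; got {self.w1_ms}, {self.w2_ms}"
            )
        if self.beta < 0:
            raise ValidationError("beta must be >= 0")


@dataclass(frozen=True)
class Block:
    """Half-open index interval [onset, offset) of interest on a feature signal."""

    onset: int
    offset: int

    def __post_init__(self) -> None:
        if not (0 <= self.onset < self.offset):
            raise ValidationError(
                f"block must satisfy 0 <= onset < offset, got [{self.onset}, "
                f"{self.offset})"
            )

    @property
    def width(self) -> int:
        return self.offset - self.onset


# ---------------------------------------------------------------------------
# Method I: local maxima / minima (Billauer)
# ---------------------------------------------------------------------------

def detect_billauer(record: PPGRecord,
                    params: BillauerParams = BillauerParams()) -> PeakAnnotation:
    """Alternating peak/valley search with amplitude excursion ``delta``.

    A running maximum is emitted as a peak at the moment the signal drops
    below (running max - delta); the state then flips to valley search and
    symmetrically back. Dips shallower than ``delta`` do not terminate a
    peak search, which makes the detector robust to small ripples but blind
    to any signal whose total excursion is below ``delta``.
    """
    if params.delta <= 0:
        raise ValidationError("delta must be > 0")
    if params.use_bandpass:
        x = butterworth_zero_phase(
            record, FilterSpec("bandpass", high_hz=params.f2, low_hz=params.f1)
        ).values
    else:
        x = np.asarray(record.samples, dtype=float)
    if params.normalize:
        scale = np.max(np.abs(x))
        if scale > 0:
            x = x / scale

    peaks: list[int] = []
    mx, mn = -np.inf, np.inf
    mxpos = 0
    looking_for_max = True
    for i, v in enumerate(x):
        if v > mx:
            mx, mxpos = v, i
        if v < mn:
            mn = v
        if looking_for_max:
            if v < mx - params.delta:
                peaks.append(mxpos)
                mn = v
                looking_for_max = False
        else:
            if v > mn + params.delta:
                mx, mxpos = v, i
                looking_for_max = True
    return annotation_from_indices(peaks, record.fs)


# ---------------------------------------------------------------------------
# Method II: first derivative with adaptive thresholds (Li-style)
# ---------------------------------------------------------------------------

def _initial_thresholds(d: np.ndarray, fs: float,
                        params: LiParams) -> tuple[float, float]:
    """Initial derivative-amplitude and beat-interval estimates.

    Averages, over a 2 s selective window at the start of each equal
    division, the maximum derivative amplitude and the spacing of prominent
    derivative peaks. Returns (mean amplitude, mean interval in samples);
    amplitude is NaN when the windows contain no positive slope at all.
    """
    n = d.size
    swin = ms_to_samples(params.selective_window_s * 1000.0, fs)
    div_len = max(n // params.n_divisions, swin)
    amps: list[float] = []
    intervals: list[float] = []
    for i in range(params.n_divisions):
        s0 = i * div_len
        seg = d[s0:s0 + swin]
        if seg.size < 2:
            continue
        m = float(seg.max())
        if m <= 0:
            continue
        amps.append(m)
        locs, _ = sps.find_peaks(seg, height=0.5 * m,
                                 distance=max(1, ms_to_samples(250.0, fs)))
        if locs.size >= 2:
            intervals.extend(np.diff(locs).tolist())
    amp = float(np.mean(amps)) if amps else float("nan")
    interval = float(np.mean(intervals)) if intervals else 0.8 * fs
    return amp, interval


def detect_li(record: PPGRecord, params: LiParams = LiParams()) -> PeakAnnotation:
    """First-derivative delineator with adaptive amplitude/interval gates.

    Pipeline: zero-phase low-pass -> first difference -> prominent
    derivative maxima (maximal inflections of the upslope) -> the following
    negative-going zero crossing of the derivative marks the systolic-peak
    candidate. Candidates too close to the previous accepted beat are
    rejected; both thresholds are updated beat-by-beat as running means of
    recently accepted beats.
    """
    fs = record.fs
    swin = ms_to_samples(params.selective_window_s * 1000.0, fs)
    if len(record) < swin:
        raise ValidationError(
            f"record of {len(record)} samples is shorter than one "
            f"{params.selective_window_s} s selective window"
        )
    filt = butterworth_zero_phase(
        record, FilterSpec("lowpass", high_hz=params.lowpass_hz)
    )
    d = first_difference(filt).values
    x = filt.values

    amp0, interval0 = _initial_thresholds(d, fs, params)
    if not np.isfinite(amp0):
        return annotation_from_indices([], fs)
    amp_thr = params.amplitude_factor * amp0
    interval = interval0

    # negative-going zero crossings of the derivative = signal local maxima
    inflections, _ = sps.find_peaks(d)
    recent_amps: deque[float] = deque([amp0], maxlen=8)
    recent_ints: deque[float] = deque(maxlen=8)
    peaks: list[int] = []
    last_peak = -np.inf
    for m_idx in inflections:
        a = d[m_idx]
        gap = m_idx - last_peak
        relaxed = gap > params.interval_factor_high * interval
        if a < amp_thr and not (relaxed and a >= 0.5 * amp_thr):
            continue
        # candidate peak: next negative-going zero crossing of the derivative
        nz = np.nonzero(d[m_idx + 1:] <= 0)[0]
        if nz.size == 0:
            continue
        c = m_idx + int(nz[0])  # d[c] > 0 >= d[c+1]
        p = c if (c + 1 >= x.size or x[c] >= x[c + 1]) else c + 1
        if p - last_peak < params.interval_factor_low * interval:
            continue
        if np.isfinite(last_peak):
            recent_ints.append(p - last_peak)
            interval = float(np.mean(recent_ints))
        recent_amps.append(float(a))
        amp_thr = params.amplitude_factor * float(np.mean(recent_amps))
        peaks.append(p)
        last_peak = p
    return annotation_from_indices(peaks, fs)


# ---------------------------------------------------------------------------
# Method III: slope sum with adaptive threshold (Zong-style)
# ---------------------------------------------------------------------------

def detect_zong(record: PPGRecord, params: ZongParams = ZongParams()) -> PeakAnnotation:
    """Slope-sum pulse detector mapped to systolic-peak positions.

    The SSF of the low-passed signal is scanned for upward crossings of an
    adaptive threshold; accepted pulses update the threshold base and yield
    an onset via a backward 1%-of-maximum search with a phase-shift
    compensation. Because the original formulation detects pulses (onsets)
    rather than systolic peaks, the returned index is the maximum of the
    band-limited signal within two search windows after the onset, making
    the output comparable with systolic-peak annotations.
    """
    params.validate()
    fs = record.fs
    n_init = ms_to_samples(params.init_seconds * 1000.0, fs)
    if len(record) <= n_init:
        raise ValidationError(
            f"record of {len(record)} samples does not cover the "
            f"{params.init_seconds} s threshold initialization span"
        )
    filt = butterworth_zero_phase(
        record, FilterSpec("lowpass", high_hz=params.lowpass_hz)
    )
    ssf = slope_sum(filt, params.ssf_window_ms).values
    x = filt.values
    n = ssf.size

    base = 3.0 * float(np.mean(ssf[:n_init]))
    thr = params.threshold_fraction * base
    search = ms_to_samples(params.search_ms, fs)
    refractory = ms_to_samples(params.refractory_ms, fs)
    phase = ms_to_samples(params.phase_adjust_ms, fs)

    peaks: list[int] = []
    last_event = -np.inf
    for i in range(1, n):
        if not (ssf[i] > thr >= ssf[i - 1]):
            continue
        if i - last_event < refractory:
            continue
        lo = max(0, i - search)
        hi = min(n, i + search + 1)
        pulse_min = float(np.min(ssf[lo:i + 1]))
        pulse_max = float(np.max(ssf[i:hi]))
        if base <= 0 or (pulse_max - pulse_min) < \
                params.accept_min_excursion_fraction * base:
            continue
        # backward onset search: latest sample where SSF is still above
        # onset_fraction * pulse max, then compensate the low-pass lag
        k = i
        while k > 0 and ssf[k] > params.onset_fraction * pulse_max:
            k -= 1
        onset = max(0, k + 1 - phase)
        # systolic apex: maximum of the band-limited signal between the
        # pulse onset and the end of the post-crossing max-search window
        w_end = min(n, max(onset + 2 * search, i + search) + 1)
        peak = onset + int(np.argmax(x[onset:w_end]))
        peaks.append(peak)
        base = pulse_max
        thr = params.threshold_fraction * base
        last_event = i

    # enforce the refractory contract on the emitted peak positions as well
    kept: list[int] = []
    for p in sorted(set(peaks)):
        if not kept or p - kept[-1] >= refractory:
            kept.append(p)
    return annotation_from_indices(kept, fs)


# ---------------------------------------------------------------------------
# Method IV: two event-related moving averages with dynamic threshold
# ---------------------------------------------------------------------------

def generate_blocks(ma_peak: FeatureSignal | np.ndarray,
                    thr1: FeatureSignal | np.ndarray) -> list[Block]:
    """Maximal runs where the peak-scale moving average exceeds THR1."""
    a = ma_peak.values if isinstance(ma_peak, FeatureSignal) else np.asarray(ma_peak)
    b = thr1.values if isinstance(thr1, FeatureSignal) else np.asarray(thr1)
    if a.shape != b.shape:
        raise ValidationError(
            f"ma_peak and thr1 lengths differ: {a.size} vs {b.size}"
        )
    mask = np.concatenate(([False], a > b, [False]))
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    onsets, offsets = edges[0::2], edges[1::2]
    return [Block(int(on), int(off)) for on, off in zip(onsets, offsets)]


def reject_blocks(blocks: list[Block], thr2_samples: int) -> list[Block]:
    """Keep blocks at least ``thr2_samples`` wide (anticipated systolic width)."""
    if thr2_samples < 1:
        raise ValidationError("thr2_samples must be >= 1")
    return [b for b in blocks if b.width >= thr2_samples]


def detect_elgendi(record: PPGRecord,
                   params: ElgendiParams = ElgendiParams()) -> PeakAnnotation:
    """Two event-related moving averages with a dynamic offset threshold.

    Stages: bandpass f1-f2 -> clip above zero -> square (z) ->
    MApeak = MA(z, W1), MAbeat = MA(z, W2); THR1 = MAbeat + beta * mean(z);
    blocks of interest are maximal runs with MApeak > THR1; blocks narrower
    than W1 (in samples, THR2) are rejected; each surviving block yields the
    argmax of z within it. The threshold scales with the squared signal, so
    detections are invariant to positive amplitude scaling of the record.
    """
    params.validate(record.fs)
    fs = record.fs
    w2 = odd_window_samples(params.w2_ms, fs)
    if len(record) < w2:
        raise ValidationError(
            f"record of {len(record)} samples is shorter than the beat "
            f"moving-average window ({w2} samples)"
        )
    y = butterworth_zero_phase(
        record, FilterSpec("bandpass", high_hz=params.f2, low_hz=params.f1)
    )
    z = square(clip_above_zero(y))
    ma_peak = moving_average(z, params.w1_ms, stage="ma_peak")
    ma_beat = moving_average(z, params.w2_ms, stage="ma_beat")
    alpha = params.beta * float(np.mean(z.values))
    thr1 = ma_beat.values + alpha
    blocks = generate_blocks(ma_peak.values, thr1)
    thr2 = odd_window_samples(params.w1_ms, fs)
    blocks = reject_blocks(blocks, thr2)
    zv = z.values
    peaks = [b.onset + int(np.argmax(zv[b.onset:b.offset])) for b in blocks]
    return annotation_from_indices(peaks, fs)


DETECTORS = {
    "billauer": (detect_billauer, BillauerParams),
    "li": (detect_li, LiParams),
    "zong": (detect_zong, ZongParams),
    "elgendi": (detect_elgendi, ElgendiParams),
}
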