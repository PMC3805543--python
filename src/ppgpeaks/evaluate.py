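"""Detection scoring: one-to-one peak matching and pooled statistics.

A detection matches an annotated systolic peak when the two lie within a
tolerance window (±50 ms by convention, inclusive). Pairing is one-to-one
and greedy in order of increasing absolute time difference; with beats
separated by far more than the tolerance — guaranteed by cardiac refractory
physiology — this equals the optimal bipartite matching. The statistics are
sensitivity SE = TP/(TP+FN), positive predictivity +P = TP/(TP+FP), and the
overall accuracy (SE + +P)/2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .signal_io import PeakAnnotation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalResult:
    """TP/FP/FN counts plus derived rates at a given matching tolerance."""

    tp: int
    fp: int
    fn: int
    se: float
    ppv: float
    overall: float
    tolerance_ms: float

    @property
    def n_truth(self) -> int:
        return self.tp + self.fn

    @property
    def n_detected(self) -> int:
        return self.tp + self.fp


def _result_from_counts(tp: int, fp: int, fn: int, tolerance_ms: float) -> EvalResult:
    if tp + fn > 0:
        se = tp / (tp + fn)
    else:
        logger.warning("no annotated peaks; SE defined as 1.0 (vacuous)")
        se = 1.0
    if tp + fp > 0:
        ppv = tp / (tp + fp)
    else:
        logger.warning("no detections; +P defined as 1.0 (vacuous)")
        ppv = 1.0
    return EvalResult(tp, fp, fn, se, ppv, (se + ppv) / 2.0, tolerance_ms)


def match_peaks(truth: PeakAnnotation, detected: PeakAnnotation,
                tolerance_ms: float = 50.0,
                fs: float | None = None) -> EvalResult:
    """Match detections to annotations one-to-one within ``tolerance_ms``.

    Candidate pairs within the (inclusive) tolerance are sorted by absolute
    time difference and assigned greedily; each annotation and detection
    participates in at most one pair. Matched pairs are TPs, unmatched
    annotations FNs, unmatched detections FPs.
    """
    if tolerance_ms < 0:
        raise ValidationError("tolerance_ms must be >= 0")
    if fs is None:
        fs = truth.fs
    if truth.fs != detected.fs or truth.fs != fs:
        raise ValidationError(
            f"annotations disagree on sampling rate: {truth.fs} vs {detected.fs}"
        )
    tol_samples = tolerance_ms * fs / 1000.0
    t = truth.indices
    d = detected.indices
    pairs: list[tuple[float, int, int]] = []
    for ti, tv in enumerate(t):
        # detections within tolerance of this annotation
        lo = np.searchsorted(d, tv - tol_samples, side="left")
        hi = np.searchsorted(d, tv + tol_samples, side="right")
        for di in range(int(lo), int(hi)):
            pairs.append((abs(float(d[di] - tv)), ti, di))
    pairs.sort()
    used_t = np.zeros(t.size, dtype=bool)
    used_d = np.zeros(d.size, dtype=bool)
    tp = 0
    for _, ti, di in pairs:
        if used_t[ti] or used_d[di]:
            continue
        used_t[ti] = used_d[di] = True
        tp += 1
    return _result_from_counts(tp, int(d.size) - tp, int(t.size) - tp, tolerance_ms)


def evaluate_dataset(pairs, tolerance_ms: float = 50.0) -> EvalResult:
    """Pool TP/FP/FN over (record, truth, detected) triples (micro-average).

    ``pairs`` iterates over ``(record, truth, detected)`` triples; the record
    element may be ``None`` when only the annotations are at hand. Rates are
    computed on the pooled counts, matching how per-condition tables report
    a single SE/+P from per-record counts.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValidationError("evaluate_dataset needs at least one record")
    tp = fp = fn = 0
    for _record, truth, detected in pairs:
        r = match_peaks(truth, detected, tolerance_ms)
        tp += r.tp
        fp += r.fp
        fn += r.fn
    return _result_from_counts(tp, fp, fn, tolerance_ms)
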