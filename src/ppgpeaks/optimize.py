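"""Brute-force grid search over the moving-average detector parameters.

Every valid combination of (f1, f2, W1, W2, beta) is run over a training
set, scored with pooled SE / +P, and ranked by overall accuracy. Parameter
interactions (the bandpass shapes the squared signal that both moving
averages see) rule out coordinate-wise optimization, hence the exhaustive
search. The canonical protocol optimizes on rest-condition records only
and freezes the winner for the post-exercise evaluations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .detectors import ElgendiParams, detect_elgendi
from .errors import ValidationError
from .evaluate import EvalResult, evaluate_dataset
from .signal_io import PeakAnnotation, PPGRecord


@dataclass(frozen=True)
class GridSpec:
    """Value lists for the five detector parameters; beta in percent."""

    f1_values: tuple[float, ...]
    f2_values: tuple[float, ...]
    w1_values: tuple[float, ...]  # ms
    w2_values: tuple[float, ...]  # ms
    beta_values: tuple[float, ...]  # percent of mean squared signal

    def __post_init__(self) -> None:
        for name in ("f1_values", "f2_values", "w1_values", "w2_values",
                     "beta_values"):
            vals = tuple(getattr(self, name))
            if not vals:
                raise ValidationError(f"{name} must be nonempty")
            object.__setattr__(self, name, vals)

    def combinations(self) -> Iterable[ElgendiParams]:
        """Valid parameter bundles; (f1, f2) pairs with f1 >= f2 are skipped."""
        for f1, f2, w1, w2, bpct in itertools.product(
            self.f1_values, self.f2_values, self.w1_values, self.w2_values,
            self.beta_values,
        ):
            if f1 >= f2 or w1 >= w2:
                continue
            yield ElgendiParams(f1, f2, w1, w2, bpct / 100.0)


def reconstruction_grid() -> GridSpec:
    """The full search ranges of the original optimization.

    Lower corner 0.5-1 Hz, upper corner 7-15 Hz, W1 54-111 ms in ~14 ms
    steps, W2 545-694 ms in ~30 ms steps, beta 0-10%. The published step
    sizes are not fully recoverable, so this is a reconstruction of the
    stated ranges, not a replica of the original 5,610-point grid.
    """
    return GridSpec(
        f1_values=(0.5, 1.0),
        f2_values=tuple(float(f) for f in range(7, 16)),
        w1_values=(54.0, 69.0, 83.0, 97.0, 111.0),
        w2_values=(545.0, 575.0, 605.0, 635.0, 665.0, 694.0),
        beta_values=tuple(float(b) for b in range(0, 11)),
    )


def coarse_grid() -> GridSpec:
    """A small grid around the defaults for quick searches and pipelines.

    W1 spans the systolic-duration scale (111-189 ms in 39 ms steps,
    including the 111 ms default) and W2 the beat-period scale at resting
    heart rates (667-913 ms in 123 ms steps, including the 667 ms default).
    """
    return GridSpec(
        f1_values=(0.5,),
        f2_values=(8.0,),
        w1_values=(111.0, 150.0, 189.0),
        w2_values=(667.0, 790.0, 913.0),
        beta_values=(0.0, 2.0, 5.0),
    )


@dataclass(frozen=True)
class GridResult:
    """All evaluated rows, best first."""

    rows: tuple[tuple[ElgendiParams, EvalResult], ...]
    n_iterations: int

    @property
    def best(self) -> tuple[ElgendiParams, EvalResult]:
        return self.rows[0]


def _rank_key(row: tuple[ElgendiParams, EvalResult]):
    p, ev = row
    # overall accuracy descending; ties: higher SE, then narrower W1,
    # smaller offset, lower f2, narrower W2 — a deterministic total order
    return (-ev.overall, -ev.se, p.w1_ms, p.beta, p.f2, p.w2_ms, p.f1)


def grid_search(
    dataset: Sequence[tuple[PPGRecord, PeakAnnotation]],
    grid: GridSpec,
    tolerance_ms: float = 50.0,
) -> GridResult:
    """Evaluate every valid grid combination over ``dataset``.

    For each parameter bundle the detector runs on every record; TP/FP/FN
    are pooled across records and rows are sorted by overall accuracy
    (descending) with deterministic tie-breaking. The whole procedure is
    deterministic given fixed inputs.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValidationError("grid_search needs a nonempty dataset")
    rows: list[tuple[ElgendiParams, EvalResult]] = []
    for params in grid.combinations():
        triples = [
            (record, truth, detect_elgendi(record, params))
            for record, truth in dataset
        ]
        rows.append((params, evaluate_dataset(triples, tolerance_ms)))
    if not rows:
        raise ValidationError("grid contains no valid parameter combination")
    rows.sort(key=_rank_key)
    return GridResult(tuple(rows), n_iterations=len(rows))
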