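"""Core record types and text I/O for PPG signals and peak annotations.

A record is a single-channel fingertip photoplethysmogram: amplitude in
arbitrary units sampled at a known rate (367 Hz for the Salus APG device
emulated by :mod:`ppgpeaks.synth`). Annotations are ordered sample indices
of systolic peaks, either hand-marked ground truth or detector output.

Conventions used throughout the package:

* sample indexing is 0-based,
* index intervals are half-open ``[onset, offset)``,
* the sampling frequency ``fs`` travels out-of-band (CLI flag / config),
  never inferred from the file contents.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .errors import ParseError, ValidationError

PathLike = Union[str, Path]

_DELIMS = re.compile(r"[,\t;]")


class Condition(str, enum.Enum):
    """Recording condition of the heat-stress study protocol."""

    REST = "rest"
    AFTER_EXERCISE_1 = "after_exercise_1"
    AFTER_EXERCISE_2 = "after_exercise_2"
    AFTER_EXERCISE_3 = "after_exercise_3"
    SYNTHETIC = "synthetic"


@dataclass(frozen=True)
class PPGRecord:
    """Raw single-channel PPG signal plus acquisition metadata.

    Parameters
    ----------
    samples
        Amplitude sequence in arbitrary units; finite, length >= 1.
    fs
        Sampling frequency in Hz (> 0). The study device samples at 367 Hz.
    record_id
        Opaque identifier used to tag derived feature signals.
    condition
        Protocol condition the record belongs to.
    """

    samples: np.ndarray
    fs: float
    record_id: str = ""
    condition: Condition = Condition.SYNTHETIC

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValidationError("record must hold a 1-D signal of length >= 1")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("record samples must all be finite")
        if not (self.fs > 0):
            raise ValidationError(f"sampling frequency must be > 0, got {self.fs}")
        samples.setflags(write=False)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "condition", Condition(self.condition))

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self)) / self.fs


@dataclass(frozen=True)
class PeakAnnotation:
    """Strictly increasing systolic-peak sample indices at sampling rate ``fs``."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        indices = np.asarray(self.indices, dtype=np.int64).ravel()
        if indices.size and indices.min() < 0:
            raise ValidationError("peak indices must be non-negative")
        if indices.size > 1 and not np.all(np.diff(indices) > 0):
            raise ValidationError("peak indices must be strictly increasing")
        if not (self.fs > 0):
            raise ValidationError(f"sampling frequency must be > 0, got {self.fs}")
        indices.setflags(write=False)
        object.__setattr__(self, "indices", indices)

    def __len__(self) -> int:
        return int(self.indices.size)

    @property
    def times_s(self) -> np.ndarray:
        return self.indices / self.fs

    def validate_against(self, record: PPGRecord) -> None:
        """Check that every index falls inside ``record`` and rates agree."""
        if self.fs != record.fs:
            raise ValidationError(
                f"annotation fs {self.fs} != record fs {record.fs}"
            )
        if len(self) and self.indices[-1] >= len(record):
            raise ValidationError("annotation index beyond record length")


def annotation_from_indices(indices: Iterable[int], fs: float) -> PeakAnnotation:
    """Build an annotation from possibly unsorted / duplicated indices."""
    arr = np.unique(np.asarray(list(indices), dtype=np.int64))
    return PeakAnnotation(arr, fs)


def _data_lines(path: PathLike) -> list[str]:
    text = Path(path).read_text(encoding="utf-8")
    lines = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            lines.append(line)
    return lines


def read_record(
    path: PathLike,
    fs: float,
    record_id: str | None = None,
    condition: Condition | str = Condition.SYNTHETIC,
) -> PPGRecord:
    """Read a delimited-text PPG record.

    Accepts one numeric column (amplitude) or two columns (time, amplitude);
    the delimiter (comma / tab / semicolon / whitespace) is autodetected.
    ``#`` starts a comment. The amplitude is always the last column.
    """
    if not (fs > 0):
        raise ValidationError(f"sampling frequency must be > 0, got {fs}")
    lines = _data_lines(path)
    if not lines:
        raise ParseError(f"no numeric data in {path}")
    values = []
    for lineno, line in enumerate(lines, start=1):
        fields = _DELIMS.split(line) if _DELIMS.search(line) else line.split()
        fields = [f for f in (f.strip() for f in fields) if f]
        if not (1 <= len(fields) <= 2):
            raise ParseError(f"{path}: expected 1 or 2 columns, got {len(fields)}")
        try:
            values.append(float(fields[-1]))
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric value {fields[-1]!r} "
                             f"on data line {lineno}") from exc
    if record_id is None:
        record_id = Path(path).stem
    return PPGRecord(np.asarray(values), fs, record_id, Condition(condition))


def write_record(record: PPGRecord, path: PathLike) -> None:
    """Write one amplitude per line, full double precision."""
    Path(path).write_text(
        "\n".join(repr(float(v)) for v in record.samples) + "\n", encoding="utf-8"
    )


def read_annotation(path: PathLike, fs: float) -> PeakAnnotation:
    """Read peak indices (one integer per line, ``#`` comments allowed).

    Output is sorted and deduplicated; negative indices are rejected.
    """
    if not (fs > 0):
        raise ValidationError(f"sampling frequency must be > 0, got {fs}")
    indices = []
    for line in _data_lines(path):
        try:
            idx = int(line)
        except ValueError as exc:
            raise ParseError(f"{path}: non-integer annotation line {line!r}") from exc
        if idx < 0:
            raise ValidationError(f"{path}: negative peak index {idx}")
        indices.append(idx)
    return annotation_from_indices(indices, fs)


def write_annotation(annotation: PeakAnnotation, path: PathLike) -> None:
    Path(path).write_text(
        "".join(f"{int(i)}\n" for i in annotation.indices), encoding="utf-8"
    )
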