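"""Labeled RR-interval sequences and the plain two-column CSV dialect.

An :class:`RRISequence` is the pipeline's common currency: an ordered stream
of RR intervals (seconds) with a per-interval binary atrial-fibrillation
label and provenance (record id, 1-based start index in the source stream).

The CSV dialect is deliberately minimal so fixtures stay portable:
header ``interval_s,af_label``, one row per interval, UTF-8, ``.`` decimal
separator, intervals written with 6 decimal places.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InputOutputError, ValidationError

CSV_HEADER = "interval_s,af_label"

# Physiological plausibility bounds for a single RR interval, in seconds.
# 0.2 s ~ 300 bpm, 2.0 s ~ 30 bpm; anything outside is treated as invalid.
RR_MIN_S = 0.2
RR_MAX_S = 2.0


@dataclass
class RRISequence:
    """An ordered stream of RR intervals with per-interval rhythm labels.

    Parameters
    ----------
    intervals
        RR intervals in seconds, all strictly positive.
    beat_labels
        Binary labels, one per interval; 1 marks atrial fibrillation. Each
        interval carries the label of its *terminating* beat.
    record_id
        Identifier of the source record (synthetic or ingested).
    start_index
        1-based position of the first interval within its source stream.
    """

    intervals: np.ndarray
    beat_labels: np.ndarray
    record_id: str = ""
    start_index: int = 1

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=np.float64)
        self.beat_labels = np.asarray(self.beat_labels)
        if self.intervals.ndim != 1 or self.beat_labels.ndim != 1:
            raise ValidationError("intervals and beat_labels must be 1-D")
        if len(self.intervals) != len(self.beat_labels):
            raise ValidationError(
                f"length mismatch: {len(self.intervals)} intervals vs "
                f"{len(self.beat_labels)} labels"
            )
        if len(self.intervals) and not np.all(self.intervals > 0):
            raise ValidationError("all intervals must be > 0 s")
        if not np.isin(self.beat_labels, (0, 1)).all():
            raise ValidationError("beat labels must be strictly binary (0/1)")
        self.beat_labels = self.beat_labels.astype(np.int8)
        if self.start_index < 1:
            raise ValidationError("start_index is 1-based and must be >= 1")

    def __len__(self) -> int:
        return len(self.intervals)

    def concat(self, other: "RRISequence") -> "RRISequence":
        """Append ``other``; keeps this sequence's provenance."""
        return RRISequence(
            intervals=np.concatenate([self.intervals, other.intervals]),
            beat_labels=np.concatenate([self.beat_labels, other.beat_labels]),
            record_id=self.record_id,
            start_index=self.start_index,
        )


def write_csv(seq: RRISequence, path: str | Path) -> None:
    """Write a sequence in the two-column CSV dialect (6 decimal places)."""
    path = Path(path)
    lines = [CSV_HEADER]
    for rr, lab in zip(seq.intervals, seq.beat_labels):
        lines.append(f"{rr:.6f},{int(lab)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_csv(path: str | Path, record_id: str | None = None) -> RRISequence:
    """Read a sequence from the two-column CSV dialect."""
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"no such file: {path}")
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].strip() != CSV_HEADER:
        raise ValidationError(
            f"{path}: expected header '{CSV_HEADER}', got "
            f"{lines[0].strip() if lines else '<empty file>'!r}"
        )
    intervals, labels = [], []
    for k, ln in enumerate(lines[1:], start=2):
        parts = ln.split(",")
        if len(parts) != 2:
            raise ValidationError(f"{path}:{k}: expected 2 columns, got {len(parts)}")
        try:
            intervals.append(float(parts[0]))
            labels.append(int(parts[1]))
        except ValueError as exc:
            raise ValidationError(f"{path}:{k}: {exc}") from exc
    return RRISequence(
        intervals=np.array(intervals),
        beat_labels=np.array(labels),
        record_id=record_id if record_id is not None else path.stem,
    )
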