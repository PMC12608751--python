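"""Convert R-peak and rhythm annotations into labeled RRI sequences.

Intervals are derived as first differences of annotated R-peak sample
indices divided by the sampling rate (the AF Holter databases are
annotated at 250 Hz), so they are kept in seconds end to end. Rhythm
annotations such as ``(AFIB`` or ``(N`` form a step function over sample
positions: each beat inherits the most recent rhythm code at or before
its sample index, and each interval takes the label of its *terminating*
beat — an interval is only observable once its closing R-peak occurs.

Two on-disk forms are supported:

* the ``rdann``-style text export of PhysioNet annotations (whitespace
  columns: elapsed time, sample index, symbol, sub, chan, num, optional
  aux rhythm string; rhythm changes carry the ``+`` symbol), and
* the plain two-column CSV dialect of :mod:`afedge.sequence`.

No ectopic or artifact filtering is applied, and no R-peak *detection* is
performed — expert annotations are assumed upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import EmptyInputError, InputOutputError, ValidationError
from .sequence import RRISequence, read_csv

logger = logging.getLogger(__name__)

#: rhythm codes counted as atrial fibrillation by default; atrial flutter
#: "(AFL" and everything else count as non-AF unless configured otherwise
DEFAULT_AF_CODES = frozenset({"(AFIB"})

KNOWN_RHYTHM_CODES = frozenset(
    {"(AFIB", "(AFL", "(N", "(NSR", "(J", "(AB", "(B", "(BII", "(IVR",
     "(P", "(PREX", "(SBR", "(SVTA", "(T", "(VFL", "(VT"})


@dataclass
class BeatAnnotations:
    """R-peak sample positions plus the rhythm-change step function.

    ``rhythm_changes`` is an ordered list of ``(sample_index, code)`` pairs;
    each code stays in force until the next change.
    """

    sample_indices: np.ndarray
    sampling_rate: float = 250.0
    rhythm_changes: list[tuple[int, str]] = field(default_factory=list)
    record_id: str = ""

    def __post_init__(self) -> None:
        self.sample_indices = np.asarray(self.sample_indices, dtype=np.int64)
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be > 0")
        if len(self.sample_indices) > 1 and not np.all(
                np.diff(self.sample_indices) > 0):
            raise ValidationError(
                f"record {self.record_id!r}: R-peak sample indices must be "
                "strictly increasing")
        if any(self.rhythm_changes[k][0] > self.rhythm_changes[k + 1][0]
               for k in range(len(self.rhythm_changes) - 1)):
            raise ValidationError(
                f"record {self.record_id!r}: rhythm changes must be sorted "
                "by sample index")


def rr_from_peaks(ann: BeatAnnotations) -> RRISequence:
    """Derive the RRI sequence from R-peak positions (labels all zero).

    interval i = (peak[i+1] - peak[i]) / sampling_rate, in seconds;
    output length is n_peaks - 1.
    """
    n = len(ann.sample_indices)
    if n < 2:
        raise EmptyInputError(
            f"record {ann.record_id!r}: need >= 2 R-peaks to form an "
            f"interval, got {n}")
    intervals = np.diff(ann.sample_indices) / ann.sampling_rate
    return RRISequence(intervals, np.zeros(n - 1, dtype=np.int8),
                       record_id=ann.record_id)


def label_beats(ann: BeatAnnotations,
                af_codes: Iterable[str] = DEFAULT_AF_CODES) -> np.ndarray:
    """Per-interval binary AF labels under the terminating-beat convention.

    Each beat inherits the rhythm code in force at its sample index (the
    most recent change at or before it); beat label = 1 iff that code is
    in ``af_codes``. Interval i takes the label of beat i+1, the beat that
    closes it.
    """
    af_codes = frozenset(af_codes)
    peaks = ann.sample_indices
    if len(peaks) < 2:
        raise EmptyInputError(
            f"record {ann.record_id!r}: need >= 2 R-peaks to label intervals")
    if not ann.rhythm_changes or ann.rhythm_changes[0][0] > peaks[0]:
        raise ValidationError(
            f"record {ann.record_id!r}: no rhythm code in force at the "
            f"first beat (sample {int(peaks[0])})")
    change_samples = np.array([s for s, _ in ann.rhythm_changes])
    codes = [c for _, c in ann.rhythm_changes]
    # index of most recent change at or before each peak
    idx = np.searchsorted(change_samples, peaks, side="right") - 1
    beat_is_af = np.array([codes[j] in af_codes for j in idx], dtype=np.int8)
    return beat_is_af[1:]  # terminating beat of interval i is beat i+1


def rri_from_annotations(ann: BeatAnnotations,
                         af_codes: Iterable[str] = DEFAULT_AF_CODES
                         ) -> RRISequence:
    """Compose interval derivation and rhythm labeling for one record."""
    seq = rr_from_peaks(ann)
    seq.beat_labels = label_beats(ann, af_codes)
    return seq


def read_rdann_text(path: str | Path, sampling_rate: float = 250.0,
                    record_id: str | None = None) -> BeatAnnotations:
    """Parse an rdann-style text annotation file.

    Rows whose symbol is ``+`` are rhythm changes (aux column holds the
    code); every other row is a beat. Unknown rhythm codes are kept but
    logged, and are treated as non-AF downstream.
    """
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"no such annotation file: {path}")
    record_id = record_id if record_id is not None else path.stem
    peaks: list[int] = []
    changes: list[tuple[int, str]] = []
    for k, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        tok = line.split()
        if len(tok) < 3:
            raise ValidationError(f"{path}:{k}: expected >= 3 columns")
        try:
            sample = int(tok[1])
        except ValueError as exc:
            raise ValidationError(f"{path}:{k}: bad sample index {tok[1]!r}") \
                from exc
        symbol = tok[2]
        if symbol == "+":
            if len(tok) < 7:
                raise ValidationError(
                    f"{path}:{k}: rhythm change without aux code")
            code = tok[6]
            if code not in KNOWN_RHYTHM_CODES:
                logger.warning("%s:%d: unknown rhythm code %r (treated as "
                               "non-AF)", path, k, code)
            changes.append((sample, code))
        else:
            peaks.append(sample)
    logger.info("record %s: %d beats, %d rhythm changes", record_id,
                len(peaks), len(changes))
    return BeatAnnotations(np.array(peaks, dtype=np.int64), sampling_rate,
                           changes, record_id=record_id)


def write_rdann_text(ann: BeatAnnotations, path: str | Path,
                     beat_symbol: str = "N") -> None:
    """Write annotations in the rdann text layout (round-trip partner)."""
    rows = [(int(s), beat_symbol, "") for s in ann.sample_indices]
    rows += [(int(s), "+", code) for s, code in ann.rhythm_changes]
    rows.sort(key=lambda r: (r[0], r[1] != "+"))  # change precedes beat at a tie
    lines = []
    for sample, symbol, aux in rows:
        t = sample / ann.sampling_rate
        stamp = f"{int(t // 60)}:{t % 60:06.3f}"
        line = f"{stamp:>12} {sample:>8} {symbol:>5} {0:>4} {0:>4} {0:>4}"
        if aux:
            line += f"\t{aux}"
        lines.append(line)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_record(path: str | Path, format: str = "csv",
                af_codes: Iterable[str] = DEFAULT_AF_CODES,
                sampling_rate: float = 250.0) -> RRISequence:
    """Read one record as a labeled RRI sequence.

    ``format='wfdb'`` expects the rdann text annotation layout;
    ``format='csv'`` the two-column interval dialect.
    """
    if format == "csv":
        return read_csv(path)
    if format == "wfdb":
        ann = read_rdann_text(path, sampling_rate=sampling_rate)
        return rri_from_annotations(ann, af_codes)
    raise ValidationError(f"unknown format {format!r}; expected wfdb|csv")
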