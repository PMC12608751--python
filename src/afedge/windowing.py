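"""Sliding-window segmentation, majority AF labeling, and the random split.

A labeled RRI stream is cut into overlapping fixed-length windows
(default length L = 40 intervals, step 1). Each window receives a binary
label by the majority rule: AF iff it contains at least T AF-labeled
intervals (default T = 20 = L/2; a tie at exactly T counts as AF).
Windows never span record boundaries.

The default train/test split shuffles *windows* uniformly, which leaks
overlapping windows between the two sides; a record-level mode is provided
for leakage-safe generalization estimates and the window mode logs a
warning when used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigError, SplitError, TooShortError, ValidationError
from .sequence import RRISequence

logger = logging.getLogger(__name__)


@dataclass
class WindowingConfig:
    """Window length, step and AF-count threshold, all in beats."""

    window_len: int = 40
    step: int = 1
    af_threshold: int = 20

    def validate(self) -> None:
        if self.window_len < 1:
            raise ConfigError("window_len must be >= 1")
        if not (1 <= self.step <= self.window_len):
            raise ConfigError("step must satisfy 1 <= step <= window_len")
        if not (1 <= self.af_threshold <= self.window_len):
            raise ConfigError("af_threshold must satisfy 1 <= T <= window_len")

    def to_dict(self) -> dict:
        return {"window_len": self.window_len, "step": self.step,
                "af_threshold": self.af_threshold}

    @classmethod
    def from_dict(cls, d: dict) -> "WindowingConfig":
        cfg = cls(**{k: int(v) for k, v in d.items()})
        cfg.validate()
        return cfg


@dataclass
class WindowSet:
    """Fixed-length windows with binary labels and source provenance.

    ``windows`` is (n_windows, L) of interval values in seconds; ``labels``
    binary per window; ``record_ids``/``start_indices`` give, per window,
    the source record and the 1-based index of its first interval.
    """

    windows: np.ndarray
    labels: np.ndarray
    record_ids: np.ndarray
    start_indices: np.ndarray

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=np.float64)
        self.labels = np.asarray(self.labels).astype(np.int8)
        self.record_ids = np.asarray(self.record_ids, dtype=object)
        self.start_indices = np.asarray(self.start_indices, dtype=np.int64)
        if self.windows.ndim != 2:
            raise ValidationError("windows must be a 2-D matrix")
        n = self.windows.shape[0]
        if not (len(self.labels) == len(self.record_ids)
                == len(self.start_indices) == n):
            raise ValidationError("windows/labels/sources length mismatch")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("window labels must be binary")

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def window_len(self) -> int:
        return self.windows.shape[1]

    def subset(self, idx: np.ndarray) -> "WindowSet":
        return WindowSet(self.windows[idx], self.labels[idx],
                         self.record_ids[idx], self.start_indices[idx])

    @staticmethod
    def concat(sets: Sequence["WindowSet"]) -> "WindowSet":
        if not sets:
            raise ValidationError("cannot concatenate zero WindowSets")
        return WindowSet(
            np.concatenate([s.windows for s in sets]),
            np.concatenate([s.labels for s in sets]),
            np.concatenate([s.record_ids for s in sets]),
            np.concatenate([s.start_indices for s in sets]),
        )

    def save(self, path: str | Path, sidecar: dict | None = None) -> None:
        """Persist as .npz plus a JSON sidecar (config, seed, mode, counts)."""
        path = Path(path)
        np.savez(path, windows=self.windows, labels=self.labels,
                 record_ids=self.record_ids.astype(str),
                 start_indices=self.start_indices)
        meta = dict(sidecar or {})
        meta.update({"n_windows": len(self), "window_len": self.window_len,
                     "n_af": int(self.labels.sum())})
        side = path.with_suffix(path.suffix + ".json") if path.suffix != ".npz" \
            else path.with_suffix(".json")
        side.write_text(json.dumps(meta, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "WindowSet":
        with np.load(Path(path), allow_pickle=False) as z:
            return cls(z["windows"], z["labels"],
                       z["record_ids"].astype(object), z["start_indices"])


def label_window(beat_labels: np.ndarray, af_threshold: int) -> int:
    """Majority rule for one window: 1 iff at least T of its labels are AF."""
    beat_labels = np.asarray(beat_labels)
    if not np.isin(beat_labels, (0, 1)).all():
        raise ValidationError("beat labels must be binary")
    return int(int(beat_labels.sum()) >= af_threshold)


def make_windows(seq: RRISequence, cfg: WindowingConfig | None = None) -> WindowSet:
    """Cut one record into overlapping windows with majority labels.

    Window k (1-based) covers intervals ``(k-1)*step + 1 .. (k-1)*step + L``
    of the record; n_windows = floor((n - L)/step) + 1.
    """
    cfg = cfg or WindowingConfig()
    cfg.validate()
    n, L, step = len(seq), cfg.window_len, cfg.step
    if n < L:
        raise TooShortError(
            f"record {seq.record_id!r}: {n} intervals < window length {L}"
        )
    starts = np.arange(0, n - L + 1, step)
    windows = sliding_window_view(seq.intervals, L)[starts].copy()
    af_counts = sliding_window_view(seq.beat_labels, L)[starts].sum(axis=1)
    labels = (af_counts >= cfg.af_threshold).astype(np.int8)
    return WindowSet(
        windows=windows,
        labels=labels,
        record_ids=np.array([seq.record_id] * len(starts), dtype=object),
        start_indices=seq.start_index + starts,
    )


def make_windows_multi(seqs: Iterable[RRISequence],
                       cfg: WindowingConfig | None = None) -> WindowSet:
    """Window each record independently and pool; windows never cross records."""
    sets = [make_windows(s, cfg) for s in seqs]
    return WindowSet.concat(sets)


def split_windows(ws: WindowSet, train_frac: float = 0.8, seed: int = 0,
                  mode: str = "window") -> tuple[WindowSet, WindowSet]:
    """Random disjoint, exhaustive train/test partition.

    ``mode='window'`` shuffles windows uniformly (the pipeline's native
    protocol; leaks overlapping windows across the split, hence the
    warning). ``mode='record'`` keeps whole records on one side.
    """
    if not (0.0 < train_frac < 1.0):
        raise ValidationError("train_frac must lie strictly between 0 and 1")
    n = len(ws)
    if n < 2:
        raise SplitError(f"need at least 2 windows to split, got {n}")
    rng = np.random.default_rng(seed)
    if mode == "window":
        logger.warning(
            "window-level split: overlapping windows may appear on both "
            "sides; use mode='record' for leakage-safe estimates"
        )
        perm = rng.permutation(n)
        n_train = int(np.floor(train_frac * n))
        n_train = min(max(n_train, 1), n - 1)
        return ws.subset(np.sort(perm[:n_train])), ws.subset(np.sort(perm[n_train:]))
    if mode == "record":
        records = np.unique(ws.record_ids.astype(str))
        if len(records) < 2:
            raise SplitError("record-level split needs at least 2 records")
        order = rng.permutation(len(records))
        target = train_frac * n
        train_records, acc = set(), 0
        for r in records[order]:
            if acc >= target or len(train_records) == len(records) - 1:
                break
            train_records.add(r)
            acc += int((ws.record_ids.astype(str) == r).sum())
        mask = np.isin(ws.record_ids.astype(str), sorted(train_records))
        if mask.all() or not mask.any():
            raise SplitError("record-level split left one side empty")
        return ws.subset(np.where(mask)[0]), ws.subset(np.where(~mask)[0])
    raise ValidationError(f"unknown split mode {mode!r}; expected window|record")
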