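"""Sliding windows, majority labeling, and the train/test split."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afedge import (RRISequence, SplitError, TooShortError, ValidationError,
                    WindowingConfig, WindowSet, fig2_fixture, label_window,
                    make_windows, make_windows_multi, split_windows)
from afedge.errors import ConfigError


def brute_force_windows(seq: RRISequence, L: int, step: int, T: int):
    """Independent oracle: explicit slicing and per-window AF counting."""
    wins, labels = [], []
    k = 0
    while k + L <= len(seq):
        wins.append(seq.intervals[k:k + L])
        labels.append(1 if int(seq.beat_labels[k:k + L].sum()) >= T else 0)
        k += step
    return np.array(wins), np.array(labels)


def random_sequence(rng, n):
    return RRISequence(rng.uniform(0.3, 1.5, n), rng.integers(0, 2, n),
                       record_id="rand")


class TestLabelWindow:
    @pytest.mark.parametrize("n_af,threshold,expected", [
        (20, 20, 1),   # tie at exactly T is AF ("20 or more")
        (19, 20, 0),
        (0, 20, 0),
        (40, 20, 1),
    ])
    def test_majority_rule(self, n_af, threshold, expected):
        labels = np.r_[np.ones(n_af), np.zeros(40 - n_af)]
        assert label_window(labels, threshold) == expected

    def test_non_binary_rejected(self):
        with pytest.raises(ValidationError):
            label_window(np.array([0, 1, 2]), 2)


class TestMakeWindows:
    def test_worked_example_80_intervals(self):
        seq = fig2_fixture()
        ws = make_windows(seq, WindowingConfig())
        assert len(ws) == 41
        assert ws.labels[0] == 0      # all non-AF
        assert ws.labels[-1] == 1     # all AF
        # first window meeting the threshold: window 21 holds 20 AF intervals
        assert ws.labels[:20].sum() == 0
        assert np.all(ws.labels[20:] == 1)

    def test_exact_boundary_single_window(self, rng):
        seq = random_sequence(rng, 40)
        ws = make_windows(seq, WindowingConfig())
        assert len(ws) == 1
        assert np.array_equal(ws.windows[0], seq.intervals)

    def test_too_short_is_explicit_error(self, rng):
        with pytest.raises(TooShortError):
            make_windows(random_sequence(rng, 39), WindowingConfig())

    def test_sources_are_one_based(self, rng):
        seq = random_sequence(rng, 45)
        ws = make_windows(seq, WindowingConfig())
        assert ws.start_indices.tolist() == list(range(1, 7))
        assert all(r == "rand" for r in ws.record_ids)

    @settings(max_examples=60, derandomize=True)
    @given(st.integers(1, 200), st.integers(1, 50), st.integers(1, 50),
           st.integers(1, 50), st.integers(0, 10 ** 6))
    def test_matches_brute_force_oracle(self, n, L, step, T, seed):
        step = min(step, L)
        T = min(T, L)
        rng = np.random.default_rng(seed)
        seq = random_sequence(rng, max(n, L))
        cfg = WindowingConfig(L, step, T)
        ws = make_windows(seq, cfg)
        bw, bl = brute_force_windows(seq, L, step, T)
        assert len(ws) == (len(seq) - L) // step + 1
        assert np.array_equal(ws.windows, bw)
        assert np.array_equal(ws.labels, bl)

    def test_flipping_one_beat_touches_only_covering_windows(self, rng):
        seq = random_sequence(rng, 100)
        cfg = WindowingConfig(40, 1, 20)
        before = make_windows(seq, cfg).labels
        j = 60
        flipped = RRISequence(seq.intervals,
                              np.where(np.arange(100) == j,
                                       1 - seq.beat_labels,
                                       seq.beat_labels), "rand")
        after = make_windows(flipped, cfg).labels
        changed = np.nonzero(before != after)[0]
        covering = [k for k in range(len(before)) if k <= j <= k + 39]
        assert set(changed.tolist()) <= set(covering)

    def test_windows_never_span_records(self, rng):
        a = random_sequence(rng, 50)
        b = RRISequence(rng.uniform(0.3, 1.5, 50),
                        rng.integers(0, 2, 50), record_id="other")
        ws = make_windows_multi([a, b], WindowingConfig())
        assert len(ws) == 11 + 11
        for w, rid, start in zip(ws.windows, ws.record_ids,
                                 ws.start_indices):
            src = a if rid == "rand" else b
            assert np.array_equal(w, src.intervals[start - 1:start + 39])

    def test_config_invariants(self):
        with pytest.raises(ConfigError):
            WindowingConfig(40, 41, 20).validate()
        with pytest.raises(ConfigError):
            WindowingConfig(40, 1, 0).validate()


class TestSplitWindows:
    def _ws(self, n, rng, record_ids=None):
        ids = record_ids if record_ids is not None else ["r0"] * n
        return WindowSet(rng.uniform(0.3, 1.5, (n, 5)),
                         rng.integers(0, 2, n), np.array(ids, dtype=object),
                         np.arange(1, n + 1))

    def test_80_20_sizes(self, rng):
        tr, te = split_windows(self._ws(100, rng), 0.8, seed=0)
        assert len(tr) == 80 and len(te) == 20

    def test_same_seed_identical_partitions(self, rng):
        ws = self._ws(57, rng)
        a = split_windows(ws, 0.8, seed=9)
        b = split_windows(ws, 0.8, seed=9)
        assert np.array_equal(a[0].start_indices, b[0].start_indices)
        assert np.array_equal(a[1].start_indices, b[1].start_indices)

    @pytest.mark.parametrize("mode", ["window", "record"])
    def test_disjoint_and_exhaustive(self, rng, mode):
        ids = [f"r{k % 3}" for k in range(60)]
        tr, te = split_windows(self._ws(60, rng, ids), 0.7, seed=3, mode=mode)
        got = sorted(tr.start_indices.tolist() + te.start_indices.tolist())
        assert got == list(range(1, 61))

    def test_record_mode_keeps_records_whole(self, rng):
        ids = [f"r{k % 3}" for k in range(60)]
        tr, te = split_windows(self._ws(60, rng, ids), 0.7, seed=3,
                               mode="record")
        assert not (set(tr.record_ids) & set(te.record_ids))

    def test_too_few_windows(self, rng):
        with pytest.raises(SplitError):
            split_windows(self._ws(1, rng), 0.8)

    def test_window_mode_warns_about_leakage(self, rng, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="afedge.windowing"):
            split_windows(self._ws(10, rng), 0.8, mode="window")
        assert "leak" in caplog.text or "overlapping" in caplog.text


class TestContainer:
    def test_save_load_round_trip(self, rng, tmp_path):
        ws = WindowSet(rng.uniform(0.3, 1.5, (7, 4)), rng.integers(0, 2, 7),
                       np.array(["a"] * 3 + ["b"] * 4, dtype=object),
                       np.arange(1, 8))
        p = tmp_path / "ws.npz"
        ws.save(p, {"note": "test"})
        back = WindowSet.load(p)
        assert np.array_equal(back.windows, ws.windows)
        assert np.array_equal(back.labels, ws.labels)
        assert back.record_ids.tolist() == ws.record_ids.tolist()
        assert (tmp_path / "ws.json").exists()
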