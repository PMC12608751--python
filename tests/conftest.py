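import numpy as np
import pytest

from afedge import (SimConfig, WindowingConfig, WindowSet, make_windows,
                    simulate_record)


def build_corpus(n_per_class: int, seed: int,
                 window_len: int = 40) -> WindowSet:
    """Overlapping-window corpus: one long NSR record and one long AF record,
    cut with the pipeline's step-1 windowing so each class contributes
    ``n_per_class`` windows."""
    n_beats = n_per_class + window_len - 1
    cfg = WindowingConfig(window_len=window_len)
    nsr = simulate_record(
        SimConfig(episode_model=[("NSR", n_beats)], seed=seed), "sim-nsr")
    af = simulate_record(
        SimConfig(episode_model=[("AF", n_beats)], seed=seed + 1), "sim-af")
    return WindowSet.concat([make_windows(nsr, cfg), make_windows(af, cfg)])


@pytest.fixture(scope="session")
def small_corpus() -> WindowSet:
    return build_corpus(300, seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
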