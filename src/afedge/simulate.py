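"""Synthetic RR-interval rhythm generator.

Emulates the two rhythm regimes the window classifier must separate:

* **Normal sinus rhythm (NSR)** — near-regular beats with modest
  variability and short-range serial correlation, modelled as an order-1
  autoregressive Gaussian around a mean RR interval, truncated to the
  physiological band (0.2, 2.0) s.
* **Atrial fibrillation (AF)** — the "irregularly irregular" ventricular
  response: independent draws from a gamma distribution with an elevated
  coefficient of variation and no serial structure, truncated identically.

Paroxysmal behaviour is scripted through an episode schedule, a list of
``(rhythm, n_beats)`` segments concatenated in order. One global integer
seed expands to per-segment substreams via a segment counter, so editing
one schedule entry never perturbs the draws of unrelated segments.

The module also ships a fixed 80-interval transition fixture (40 sinus
intervals followed by 40 AF intervals) used throughout the tests and
examples; with a 40-beat window and step 1 it yields 41 windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigError, ValidationError
from .sequence import RR_MAX_S, RR_MIN_S, RRISequence, read_csv

NSR = "NSR"
AF = "AF"

#: seed of the shipped transition fixture; bump only with the data file
FIXTURE_SEED = 20260901
FIXTURE_FILE = "fig2_transition.csv"

_MAX_REJECTION_ROUNDS = 1000


@dataclass
class SimConfig:
    """Generator parameters for both rhythm regimes.

    Defaults are physiologically plausible resting values: sinus rhythm at
    75 bpm (mean RR 0.80 s) with 50 ms beat-to-beat variability and lag-1
    autocorrelation 0.4; AF at 100 bpm (mean RR 0.60 s) with a 20%
    coefficient of variation and independent beats.
    """

    mean_rr_nsr: float = 0.80
    sd_rr_nsr: float = 0.05
    ar1_nsr: float = 0.4
    mean_rr_af: float = 0.60
    cv_af: float = 0.20
    episode_model: Sequence[tuple[str, int]] = field(
        default_factory=lambda: [(NSR, 40), (AF, 40)]
    )
    seed: int = 0

    def validate(self) -> None:
        for name, mean in (("mean_rr_nsr", self.mean_rr_nsr),
                           ("mean_rr_af", self.mean_rr_af)):
            if not (RR_MIN_S < mean < RR_MAX_S):
                raise ConfigError(
                    f"{name}={mean} outside physiological band "
                    f"({RR_MIN_S}, {RR_MAX_S}) s"
                )
        if self.sd_rr_nsr <= 0:
            raise ConfigError("sd_rr_nsr must be > 0")
        if not (0 <= self.ar1_nsr < 1):
            raise ConfigError("ar1_nsr must lie in [0, 1)")
        if self.cv_af <= 0:
            raise ConfigError("cv_af must be > 0")
        # AF must be strictly more dispersed than sinus rhythm by design;
        # the classifier's discriminability rests on this contract.
        if self.cv_af <= self.sd_rr_nsr / self.mean_rr_nsr:
            raise ConfigError(
                "cv_af must exceed the sinus coefficient of variation "
                f"({self.sd_rr_nsr / self.mean_rr_nsr:.4f})"
            )

    def to_dict(self) -> dict:
        return {
            "mean_rr_nsr": self.mean_rr_nsr,
            "sd_rr_nsr": self.sd_rr_nsr,
            "ar1_nsr": self.ar1_nsr,
            "mean_rr_af": self.mean_rr_af,
            "cv_af": self.cv_af,
            "episode_model": [[r, int(n)] for r, n in self.episode_model],
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "episode_model" in d:
            d["episode_model"] = [(str(r), int(n)) for r, n in d["episode_model"]]
        try:
            cfg = cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        cfg.validate()
        return cfg


def _truncated_ar1(n: int, mean: float, sd: float, phi: float,
                   rng: np.random.Generator) -> np.ndarray:
    """AR(1) Gaussian with stationary mean/sd, truncated by rejection.

    The innovation sd is scaled so the *stationary* marginal keeps the
    configured sd: sigma_eps = sd * sqrt(1 - phi^2). Out-of-band proposals
    redraw only the offending innovation, preserving the chain.
    """
    sigma_eps = sd * np.sqrt(1.0 - phi * phi)
    out = np.empty(n)
    # stationary start
    x = mean + sd * rng.standard_normal()
    for _ in range(_MAX_REJECTION_ROUNDS):
        if RR_MIN_S < x < RR_MAX_S:
            break
        x = mean + sd * rng.standard_normal()
    for t in range(n):
        if t > 0:
            x = mean + phi * (out[t - 1] - mean) + sigma_eps * rng.standard_normal()
            for _ in range(_MAX_REJECTION_ROUNDS):
                if RR_MIN_S < x < RR_MAX_S:
                    break
                x = mean + phi * (out[t - 1] - mean) + sigma_eps * rng.standard_normal()
        out[t] = x
    return out


def _truncated_gamma(n: int, mean: float, cv: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Independent gamma draws with given mean and CV, truncated by rejection."""
    shape = 1.0 / (cv * cv)
    scale = mean * cv * cv
    out = rng.gamma(shape, scale, size=n)
    bad = (out <= RR_MIN_S) | (out >= RR_MAX_S)
    for _ in range(_MAX_REJECTION_ROUNDS):
        k = int(bad.sum())
        if k == 0:
            break
        out[bad] = rng.gamma(shape, scale, size=k)
        bad = (out <= RR_MIN_S) | (out >= RR_MAX_S)
    return out


def simulate_segment(rhythm: str, n_beats: int, config: SimConfig | None = None,
                     rng: np.random.Generator | None = None) -> RRISequence:
    """Generate one single-rhythm segment of ``n_beats`` intervals.

    NSR segments follow the truncated AR(1) Gaussian model, AF segments
    independent truncated gamma draws; labels are constant (0 for NSR,
    1 for AF). If ``rng`` is omitted a fresh generator is derived from
    ``config.seed``.
    """
    config = config or SimConfig()
    config.validate()
    if n_beats < 1:
        raise ValidationError(f"n_beats must be >= 1, got {n_beats}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if rhythm == NSR:
        rr = _truncated_ar1(n_beats, config.mean_rr_nsr, config.sd_rr_nsr,
                            config.ar1_nsr, rng)
        labels = np.zeros(n_beats, dtype=np.int8)
    elif rhythm == AF:
        rr = _truncated_gamma(n_beats, config.mean_rr_af, config.cv_af, rng)
        labels = np.ones(n_beats, dtype=np.int8)
    else:
        raise ValidationError(f"unknown rhythm {rhythm!r}; expected 'NSR' or 'AF'")
    return RRISequence(rr, labels, record_id=f"sim-{rhythm.lower()}")


def simulate_record(config: SimConfig, record_id: str = "sim") -> RRISequence:
    """Concatenate the episode schedule into one labeled record.

    Each segment draws from its own substream seeded by
    ``(config.seed, segment_index)``, so per-beat labels reproduce the
    schedule exactly and schedule edits leave other segments' draws intact.
    """
    config.validate()
    if not config.episode_model:
        raise ValidationError("episode_model must contain at least one segment")
    parts = []
    for k, (rhythm, n_beats) in enumerate(config.episode_model):
        rng = np.random.default_rng([config.seed, k])
        parts.append(simulate_segment(rhythm, n_beats, config, rng))
    seq = parts[0]
    for p in parts[1:]:
        seq = seq.concat(p)
    seq.record_id = record_id
    return seq


def make_transition_fixture() -> RRISequence:
    """Regenerate the shipped 80-interval NSR-to-AF transition fixture.

    40 sinus intervals followed by 40 AF intervals under the default
    generator parameters with a pinned seed. The transition occurs after
    interval 40, so the per-interval labels are 40 zeros then 40 ones.
    """
    cfg = SimConfig(episode_model=[(NSR, 40), (AF, 40)], seed=FIXTURE_SEED)
    return simulate_record(cfg, record_id="fig2-transition")


def fig2_fixture() -> RRISequence:
    """Load the versioned 80-interval NSR-to-AF transition fixture.

    The fixture is shipped as a CSV data file; ``make_transition_fixture``
    regenerates it deterministically and the test suite asserts both agree.
    """
    with resources.as_file(
        resources.files("afedge.data").joinpath(FIXTURE_FILE)
    ) as p:
        return read_csv(p, record_id="fig2-transition")
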