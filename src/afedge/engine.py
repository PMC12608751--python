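"""Dependency-light single-precision forward pass for deployment parity.

This module re-implements the classifier's inference path as an explicit
per-window, per-time-step recurrence in 32-bit floats — the arithmetic a
single-precision embedded FPU would perform — entirely independent of the
vectorized training code in :mod:`afedge.model`. The two routes are held
to elementwise agreement within 1e-5 by the parity tests.

Cell equations (gate order input | forget | candidate | output):

    i = sigmoid(x W_i + h' R_i + b_i)      f = sigmoid(x W_f + h' R_f + b_f)
    g = tanh   (x W_g + h' R_g + b_g)      o = sigmoid(x W_o + h' R_o + b_o)
    c = f * c' + i * g                     h = o * tanh(c)

The backward direction consumes the reversed window and its per-step
outputs are re-reversed to input time order before concatenation, so the
pooled feature vector spans both directions at every step.
"""

from __future__ import annotations

import numpy as np

from .bundle import WeightBundle, expected_shapes, load_bundle, save_bundle  # noqa: F401 (re-export)
from .errors import ValidationError

_F32 = np.float32


def _sigmoid32(z: np.ndarray) -> np.ndarray:
    return (_F32(1.0) / (_F32(1.0) + np.exp(-z, dtype=_F32))).astype(_F32)


def lstm_cell_step(x: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray,
                   kernel: np.ndarray, recurrent_kernel: np.ndarray,
                   bias: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update in float32; returns the new (h, c)."""
    x = np.asarray(x, dtype=_F32).ravel()
    h_prev = np.asarray(h_prev, dtype=_F32).ravel()
    c_prev = np.asarray(c_prev, dtype=_F32).ravel()
    kernel = np.asarray(kernel, dtype=_F32)
    recurrent_kernel = np.asarray(recurrent_kernel, dtype=_F32)
    bias = np.asarray(bias, dtype=_F32).ravel()
    U = h_prev.shape[0]
    if kernel.shape != (x.shape[0], 4 * U) \
            or recurrent_kernel.shape != (U, 4 * U) \
            or bias.shape != (4 * U,) or c_prev.shape != (U,):
        raise ValidationError(
            f"inconsistent cell shapes: x{x.shape}, h{h_prev.shape}, "
            f"kernel{kernel.shape}, recurrent{recurrent_kernel.shape}, "
            f"bias{bias.shape}")
    z = (x @ kernel + h_prev @ recurrent_kernel + bias).astype(_F32)
    i = _sigmoid32(z[:U])
    f = _sigmoid32(z[U:2 * U])
    g = np.tanh(z[2 * U:3 * U], dtype=_F32)
    o = _sigmoid32(z[3 * U:])
    c = (f * c_prev + i * g).astype(_F32)
    h = (o * np.tanh(c, dtype=_F32)).astype(_F32)
    return h, c


def _run_direction(steps: np.ndarray, kernel: np.ndarray,
                   recurrent_kernel: np.ndarray, bias: np.ndarray,
                   units: int) -> np.ndarray:
    """Full-sequence recurrence over ``steps`` (T, F); returns (T, U)."""
    T = steps.shape[0]
    h = np.zeros(units, dtype=_F32)
    c = np.zeros(units, dtype=_F32)
    out = np.empty((T, units), dtype=_F32)
    for t in range(T):
        h, c = lstm_cell_step(steps[t], h, c, kernel, recurrent_kernel, bias)
        out[t] = h
    return out


def forward(window: np.ndarray, bundle: WeightBundle) -> float:
    """AF probability for one window of ``spec.input_len`` RR intervals."""
    spec = bundle.spec
    window = np.asarray(window, dtype=_F32).ravel()
    if window.shape[0] != spec.input_len:
        raise ValidationError(
            f"window length {window.shape[0]} != expected {spec.input_len}")
    x = ((window - _F32(bundle.input_mean)) / _F32(bundle.input_std))
    steps = x.reshape(spec.input_len, spec.input_features).astype(_F32)
    t = bundle.tensors
    h_fwd = _run_direction(steps, t["lstm_forward/kernel"],
                           t["lstm_forward/recurrent_kernel"],
                           t["lstm_forward/bias"], spec.lstm_units)
    h_bwd_rev = _run_direction(steps[::-1], t["lstm_backward/kernel"],
                               t["lstm_backward/recurrent_kernel"],
                               t["lstm_backward/bias"], spec.lstm_units)
    h_bwd = h_bwd_rev[::-1]
    concat = np.concatenate([h_fwd, h_bwd], axis=1)      # (T, 2U)
    pooled = concat.max(axis=0)                          # (2U,)
    a1 = (pooled @ t["dense_hidden/kernel"]
          + t["dense_hidden/bias"]).astype(_F32)
    r1 = np.maximum(a1, _F32(0.0))
    z = (r1 @ t["dense_output/kernel"] + t["dense_output/bias"]).astype(_F32)
    return float(_sigmoid32(z)[0])


def forward_many(windows: np.ndarray, bundle: WeightBundle) -> np.ndarray:
    """Probabilities for a stack of windows, one engine pass each."""
    windows = np.atleast_2d(np.asarray(windows))
    return np.array([forward(w, bundle) for w in windows], dtype=np.float64)
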