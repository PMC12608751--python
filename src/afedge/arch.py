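"""Layer topology of the bidirectional-LSTM window classifier.

The network consumes a window of L = 40 RR intervals (one feature per
time step) and emits a single AF probability:

    input (40, 1)
    -> LSTM forward  (full sequence, 40 units)  \\  concatenated
    -> LSTM backward (full sequence, 40 units)  /   to (40, 80)
    -> global 1-D max pooling over time         ->  80 features
    -> dense ReLU (50 units)
    -> dropout
    -> dense sigmoid (1 unit)

Per-layer trainable-parameter counts follow the standard closed forms:
an LSTM direction with U units over F input features holds
``4 * (U*(F+U) + U)`` parameters (four gates, each with input kernel,
recurrent kernel and bias); the dense layers hold ``fan_in * units +
units`` each; input, pooling and dropout hold none.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError


@dataclass(frozen=True)
class ModelSpec:
    """Sizes and rates defining the classifier topology."""

    input_len: int = 40
    input_features: int = 1
    lstm_units: int = 40
    dense_units: int = 50
    dropout_rate: float = 0.5
    output_units: int = 1

    def validate(self) -> None:
        for name in ("input_len", "input_features", "lstm_units",
                     "dense_units", "output_units"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.output_units != 1:
            raise ConfigError("the sigmoid head has exactly 1 output unit")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigError("dropout_rate must lie in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "input_len": self.input_len,
            "input_features": self.input_features,
            "lstm_units": self.lstm_units,
            "dense_units": self.dense_units,
            "dropout_rate": self.dropout_rate,
            "output_units": self.output_units,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        spec = cls(
            input_len=int(d["input_len"]),
            input_features=int(d["input_features"]),
            lstm_units=int(d["lstm_units"]),
            dense_units=int(d["dense_units"]),
            dropout_rate=float(d.get("dropout_rate", 0.5)),
            output_units=int(d.get("output_units", 1)),
        )
        spec.validate()
        return spec


def count_parameters(spec: ModelSpec) -> dict[str, int]:
    """Closed-form per-layer trainable parameter counts plus the total."""
    spec.validate()
    U, F, D = spec.lstm_units, spec.input_features, spec.dense_units
    per_direction = 4 * (U * (F + U) + U)
    dense_hidden = 2 * U * D + D
    dense_output = D * spec.output_units + spec.output_units
    counts = {
        "input": 0,
        "lstm_forward": per_direction,
        "lstm_backward": per_direction,
        "global_max_pooling": 0,
        "dense_hidden": dense_hidden,
        "dropout": 0,
        "dense_output": dense_output,
    }
    counts["total"] = sum(counts.values())
    return counts
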