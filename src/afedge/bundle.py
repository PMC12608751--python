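"""Portable weight container: JSON manifest + flat little-endian float32 blob.

The bundle holds every trained tensor in a fixed order with shapes implied
by the :class:`~afedge.arch.ModelSpec`, stored as 32-bit floats to mirror a
single-precision embedded FPU. On disk it is a pair of files sharing a
prefix: ``<prefix>.json`` (spec echo, tensor table with name, shape, byte
offset and CRC-32 checksum) and ``<prefix>.bin`` (tensors concatenated in
manifest order, little-endian float32) — a layout suitable for direct
firmware embedding. Loading verifies shapes and checksums and refuses
corrupt bundles.

Within each LSTM kernel the gate blocks are ordered
``input | forget | candidate | output`` along the trailing axis.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .arch import ModelSpec
from .errors import CorruptBundleError, ValidationError

FORMAT_VERSION = 1

#: manifest tensor order; 2 directions x 3 tensors + 2 dense layers x 2
TENSOR_NAMES = (
    "lstm_forward/kernel",
    "lstm_forward/recurrent_kernel",
    "lstm_forward/bias",
    "lstm_backward/kernel",
    "lstm_backward/recurrent_kernel",
    "lstm_backward/bias",
    "dense_hidden/kernel",
    "dense_hidden/bias",
    "dense_output/kernel",
    "dense_output/bias",
)

GATE_ORDER = ("input", "forget", "candidate", "output")


def expected_shapes(spec: ModelSpec) -> dict[str, tuple[int, ...]]:
    """Tensor shapes implied by the topology, in manifest order."""
    U, F, D, O = (spec.lstm_units, spec.input_features, spec.dense_units,
                  spec.output_units)
    per_dir = {"kernel": (F, 4 * U), "recurrent_kernel": (U, 4 * U),
               "bias": (4 * U,)}
    shapes: dict[str, tuple[int, ...]] = {}
    for direction in ("forward", "backward"):
        for name, shp in per_dir.items():
            shapes[f"lstm_{direction}/{name}"] = shp
    shapes["dense_hidden/kernel"] = (2 * U, D)
    shapes["dense_hidden/bias"] = (D,)
    shapes["dense_output/kernel"] = (D, O)
    shapes["dense_output/bias"] = (O,)
    return shapes


@dataclass
class WeightBundle:
    """All trained tensors (float32) plus the topology they realize.

    ``input_mean``/``input_std`` record an optional per-corpus input
    standardization baked in at training time (identity by default);
    every consumer applies ``(x - input_mean) / input_std``.
    """

    spec: ModelSpec
    tensors: dict[str, np.ndarray]
    format_version: int = FORMAT_VERSION
    input_mean: float = 0.0
    input_std: float = 1.0

    def __post_init__(self) -> None:
        self.tensors = {k: np.ascontiguousarray(v, dtype=np.float32)
                        for k, v in self.tensors.items()}
        self.validate()

    def validate(self) -> None:
        shapes = expected_shapes(self.spec)
        missing = set(shapes) - set(self.tensors)
        extra = set(self.tensors) - set(shapes)
        if missing or extra:
            raise ValidationError(
                f"bundle tensor names mismatch: missing {sorted(missing)}, "
                f"unexpected {sorted(extra)}")
        for name, shp in shapes.items():
            got = self.tensors[name].shape
            if tuple(got) != shp:
                raise ValidationError(
                    f"tensor {name}: expected shape {shp}, got {tuple(got)}")
        if self.input_std <= 0:
            raise ValidationError("input_std must be > 0")

    def total_parameters(self) -> int:
        return sum(int(t.size) for t in self.tensors.values())


def save_bundle(bundle: WeightBundle, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.json`` + ``<prefix>.bin``; returns both paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    table = []
    blobs = []
    offset = 0
    for name in TENSOR_NAMES:
        arr = bundle.tensors[name]
        raw = arr.astype("<f4").tobytes()
        table.append({
            "name": name,
            "shape": list(arr.shape),
            "offset": offset,
            "nbytes": len(raw),
            "crc32": zlib.crc32(raw),
        })
        blobs.append(raw)
        offset += len(raw)
    manifest = {
        "format_version": bundle.format_version,
        "byte_order": "little",
        "dtype": "float32",
        "gate_order": list(GATE_ORDER),
        "spec": bundle.spec.to_dict(),
        "input_mean": bundle.input_mean,
        "input_std": bundle.input_std,
        "tensors": table,
        "total_bytes": offset,
    }
    json_path = prefix.with_suffix(".json")
    bin_path = prefix.with_suffix(".bin")
    json_path.write_text(json.dumps(manifest, indent=2) + "\n",
                         encoding="utf-8")
    bin_path.write_bytes(b"".join(blobs))
    return json_path, bin_path


def load_bundle(prefix: str | Path) -> WeightBundle:
    """Load and verify a bundle written by :func:`save_bundle`."""
    prefix = Path(prefix)
    json_path = prefix.with_suffix(".json")
    bin_path = prefix.with_suffix(".bin")
    for p in (json_path, bin_path):
        if not p.exists():
            raise CorruptBundleError(f"missing bundle file: {p}")
    try:
        manifest = json.loads(json_path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise CorruptBundleError(f"{json_path}: invalid manifest: {exc}") \
            from exc
    if manifest.get("format_version") != FORMAT_VERSION:
        raise CorruptBundleError(
            f"{json_path}: unsupported format_version "
            f"{manifest.get('format_version')!r}")
    blob = bin_path.read_bytes()
    if len(blob) != manifest["total_bytes"]:
        raise CorruptBundleError(
            f"{bin_path}: expected {manifest['total_bytes']} bytes, "
            f"got {len(blob)}")
    spec = ModelSpec.from_dict(manifest["spec"])
    tensors: dict[str, np.ndarray] = {}
    for entry in manifest["tensors"]:
        raw = blob[entry["offset"]:entry["offset"] + entry["nbytes"]]
        if zlib.crc32(raw) != entry["crc32"]:
            raise CorruptBundleError(
                f"{bin_path}: checksum mismatch for tensor {entry['name']}")
        arr = np.frombuffer(raw, dtype="<f4").reshape(entry["shape"])
        tensors[entry["name"]] = arr.copy()
    try:
        return WeightBundle(spec, tensors,
                            format_version=manifest["format_version"],
                            input_mean=float(manifest.get("input_mean", 0.0)),
                            input_std=float(manifest.get("input_std", 1.0)))
    except ValidationError as exc:
        raise CorruptBundleError(str(exc)) from exc
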