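"""Derive a labeled RRI sequence from R-peak + rhythm annotations.

Builds a small annotation record in memory (beats at 250 Hz with an AF
episode declared by rhythm markers), writes it in the rdann text layout,
reads it back, and shows the terminating-beat labeling convention.
"""

from tempfile import TemporaryDirectory
from pathlib import Path

import numpy as np

from afedge import BeatAnnotations, read_record
from afedge.ingest import write_rdann_text

# 30 beats 0.8 s apart; rhythm switches to AF at the sample of beat 15.
peaks = np.cumsum(np.full(30, 200))
ann = BeatAnnotations(
    sample_indices=peaks,
    sampling_rate=250.0,
    rhythm_changes=[(int(peaks[0]), "(N"), (int(peaks[14]), "(AFIB")],
    record_id="demo")

with TemporaryDirectory() as tmp:
    path = Path(tmp) / "demo.txt"
    write_rdann_text(ann, path)
    seq = read_record(path, format="wfdb")

print(f"{len(ann.sample_indices)} beats -> {len(seq)} intervals "
      f"(first differences / 250 Hz)")
print(f"intervals: all {seq.intervals[0]:.1f} s")
print(f"AF-labeled intervals: {int(seq.beat_labels.sum())}")
print("labels:", "".join(map(str, seq.beat_labels)))
# Each interval takes the label of the beat that closes it, so the first
# AF interval is the one terminated by beat 15.
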