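"""Cut the shipped 80-interval transition record into majority-labeled windows.

40 sinus intervals followed by 40 AF intervals, windowed at length 40 with
step 1, yield 41 overlapping windows; a window is AF once at least 20 of
its intervals are AF-labeled.
"""

import numpy as np

from afedge import WindowingConfig, fig2_fixture, make_windows

seq = fig2_fixture()
print(f"record: {len(seq)} intervals, {int(seq.beat_labels.sum())} AF-labeled")

ws = make_windows(seq, WindowingConfig(window_len=40, step=1, af_threshold=20))
first_af = int(np.argmax(ws.labels == 1)) + 1
print(f"windows: {len(ws)}, AF-labeled: {int(ws.labels.sum())}")
print(f"window 1 label: {ws.labels[0]}  (all sinus -> non-AF)")
print(f"window {first_af} is the first AF window "
      f"(it holds {int(seq.beat_labels[first_af - 1:first_af + 39].sum())} "
      "AF intervals, reaching the threshold of 20)")
print(f"window {len(ws)} label: {ws.labels[-1]}  (all AF -> AF)")
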