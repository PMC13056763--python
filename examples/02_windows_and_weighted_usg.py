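"""Overlapping 24-h windows and the volume-weighted USG.

A 32-h void stream yields two 24-h collection windows, one ending at the
morning assessment and one at the afternoon assessment 8 h later; the
middle 16 h of voids belong to both.  The reference USG of a window is
the volume-weighted mean of its member voids.
"""

import pandas as pd

from hydrascore import extract_windows, weighted_usg, window_metrics
from hydrascore.features import Void

t0 = pd.Timestamp("2024-06-01 08:00:00")
voids = [
    Void("P1", t0 + pd.Timedelta(hours=h), volume, usg)
    for h, volume, usg in [
        (2, 300, 1.005), (6, 250, 1.008), (11, 400, 1.012), (14, 220, 1.015),
        (22.5, 520, 1.022),           # overnight-accumulated first-morning void
        (26, 310, 1.010), (31.8, 280, 1.009),
    ]
]
morning, afternoon = extract_windows(
    voids, (t0 + pd.Timedelta(hours=24), t0 + pd.Timedelta(hours=32))
)

for window in (morning, afternoon):
    met = window_metrics(window)
    print(f"{window.label:9s} window ({window.start:%H:%M} -> {window.end:%H:%M}]: "
          f"{met['void_count_24h']} voids, {met['volume_24h']:.0f} mL, "
          f"weighted USG {met['weighted_usg']:.4f}")

shared = {v.time for v in morning.voids} & {v.time for v in afternoon.voids}
print(f"voids shared by both windows: {len(shared)}")
print(f"weighted USG is volume-weighted, not a plain mean: "
      f"{weighted_usg(morning):.4f} vs "
      f"{sum(v.usg for v in morning.voids)/len(morning.voids):.4f}")
# The big concentrated first-morning void pulls the weighted mean above
# the unweighted mean of the same window.
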