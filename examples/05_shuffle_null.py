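"""Shuffle-based significance of a phase landmark.

Reaction times are randomly re-paired with respiratory phases (phase
counts preserved) B times; each shuffle is refitted and the landmark
re-extracted.  The one-sided p-value is the proportion of shuffles at
least as extreme as the observed landmark (below it, for a trough).
"""

import numpy as np
import pandas as pd

import respstart as rs
from respstart.bootstrap import StatisticSpec, landmark_pvalue

rng = np.random.default_rng(6)
spec = StatisticSpec(measure="rt_mean", condition="VSRT", muscle="1DI",
                     landmark="transition_IE")


def dataset(trough_ms):
    phases = rng.integers(1, 7, 480)
    mod = rs.evaluate(rs.transition_trough_modulation(trough_ms), phases)
    return pd.DataFrame({
        "participant": "P01", "condition": "VSRT",
        "phase": pd.array(phases, dtype="Int64"),
        "rt_1DI_ms": 162.0 + mod + 45.0 * rng.standard_normal(480),
    })


for trough, label in ((0.0, "no modulation"), (15.0, "15 ms trough")):
    nd = landmark_pvalue(dataset(trough), spec, B=10_000, seed=1)
    print(f"{label:15s}: observed {nd.observed:6.1f} ms at x=3.5, "
          f"p = {nd.p:.4f} ({nd.direction}, B = {nd.B})")
print("\nWith no injected modulation the trough is unremarkable against the"
      " shuffle null; a 15 ms trough at the inspiration->expiration"
      " transition is flagged as significant.")
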