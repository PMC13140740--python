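"""Segment a breathing temperature signal into six respiratory phases.

The temperature trace falls during inspiration and rises during
expiration, so inspiration onsets are local maxima and expiration onsets
local minima.  Each cycle is then split into equidistant thirds: I1-I3
(inspiration) and E1-E3 (expiration).
"""

import numpy as np

import respstart as rs

cfg = rs.BreathingConfig(duration_s=300.0, period_jitter_cv=0.1, noise_sd=0.02)
signal, truth = rs.generate_breathing(cfg, rng=4)
seg = rs.segment_cycles(signal)

true_insp = np.array([c.inspiration_onset_s for c in truth.cycles])
est_insp = np.array([c.inspiration_onset_s for c in seg.cycles])
errors_ms = [1000 * (t - true_insp[np.argmin(np.abs(true_insp - t))])
             for t in est_insp]

print(f"detected {len(seg)} cycles ({len(truth)} generated)")
print(f"inspiration-onset error: mean {np.mean(np.abs(errors_ms)):.1f} ms, "
      f"max {np.max(np.abs(errors_ms)):.1f} ms")

for t in (50.0, 51.5, 53.0):
    x = rs.label_phase(seg, t)
    print(f"t = {t:5.1f} s -> phase {x} ({rs.PHASE_LABELS[x]})")
print("\nBoundary errors of a few milliseconds against a ~670 ms phase bin"
      " mean that almost every cue is assigned its true respiratory phase.")
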