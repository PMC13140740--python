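"""Fit the two-harmonic mixture to per-phase reaction-time means.

T(x) = k + A1 sin(w(x-1) + theta1) + A2 sin(2w(x-1) + theta2), w = 2*pi/6,
on the six phase bins x = 1..6.  On equally spaced bins the fit is a
closed-form Fourier projection, so noiseless model data are recovered
exactly; landmarks read the curve at the transition (x = 3.5, 0.5) and
mid-phase (x = 2, 5) coordinates.
"""

import numpy as np

import respstart as rs

# phase means with a 12 ms trough at the inspiration->expiration transition
truth = rs.transition_trough_modulation(12.0)
phase_means = 162.0 + rs.evaluate(truth, np.arange(1, 7))
print("phase means (ms):", np.round(phase_means, 2))

fit = rs.fit_mixture(phase_means)
print(f"\nfit: k = {fit.k:.2f} ms, A1 = {fit.A1:.2f} ms, "
      f"theta1 = {fit.theta1:.3f} rad, A2 = {fit.A2:.2f} ms (rss {fit.rss:.2e})")
print(f"modulation amplitude (half peak-to-trough): "
      f"{rs.modulation_amplitude(fit):.2f} ms")

for kind in rs.LANDMARK_X:
    lm = rs.landmark(fit, kind, direction="trough" if "transition" in kind
                     else "peak")
    print(f"{kind:16s} x = {lm.x:3.1f} -> {lm.value:.2f} ms")
print("\nThe fitted amplitude equals the injected 12 ms and the"
      " inspiration->expiration transition (x = 3.5) shows the fastest"
      " reaction times, exactly as constructed.")
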