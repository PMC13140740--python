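"""Optional plotting helpers (requires matplotlib, extra ``plots``)."""

from __future__ import annotations

import numpy as np

from . import harmonic


def plot_phase_fit(phase_means, params: harmonic.SinusoidFitParams | None = None,
                   ax=None, label: str | None = None, ylabel: str = "RT (ms)"):
    """Six phase means with the fitted two-harmonic curve overlaid.

    Returns the matplotlib Axes.  ``params`` defaults to fitting the means.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3))
    y = np.asarray(phase_means, dtype=float)
    if params is None:
        params = harmonic.fit_mixture(y)
    x_grid = np.linspace(0.5, 6.5, 400)
    ax.plot(x_grid, harmonic.evaluate(params, x_grid), "-", lw=1.5, label=label)
    ax.plot(np.arange(1, 7), y, "o", ms=6, color=ax.lines[-1].get_color())
    ax.axvline(3.5, ls=":", lw=0.8, color="grey")  # inspiration->expiration
    ax.set_xticks(range(1, 7))
    ax.set_xticklabels(["I1", "I2", "I3", "E1", "E2", "E3"])
    ax.set_xlabel("respiratory phase")
    ax.set_ylabel(ylabel)
    if label:
        ax.legend(frameon=False)
    return ax
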