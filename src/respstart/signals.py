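"""Uniformly sampled signal container and plain-CSV I/O.

Both the breathing (temperature) channel and the EMG channels are carried
around as :class:`SampledSignal`: a start time, a sampling rate in Hz and a
1-D value array.  Signals are written to disk as 2-column CSV
(``time_s,value``) so that every artefact of a run is inspectable with a
text editor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SIGNAL_SCHEMA_VERSION = "1"


@dataclass
class SampledSignal:
    """A uniformly sampled time series.

    Parameters
    ----------
    values :
        1-D sample array.
    rate_hz :
        Sampling rate in Hz (> 0).
    t0_s :
        Time of the first sample, in seconds.
    """

    values: np.ndarray
    rate_hz: float
    t0_s: float = 0.0
    channel: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.floating):
            self.values = self.values.astype(float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be > 0")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0_s + np.arange(len(self.values)) / self.rate_hz

    def index_at(self, t_s: float) -> int:
        """Index of the sample at (or immediately before) time ``t_s``."""
        return int(np.floor((t_s - self.t0_s) * self.rate_hz + 1e-9))

    def slice_seconds(self, start_s: float, stop_s: float) -> "SampledSignal":
        """Sub-signal covering [start_s, stop_s); clipped to the record."""
        i0 = max(0, self.index_at(start_s))
        i1 = min(len(self.values), self.index_at(stop_s))
        return SampledSignal(
            self.values[i0:i1], self.rate_hz, self.t0_s + i0 / self.rate_hz, self.channel
        )


def write_signal_csv(signal: SampledSignal, path: str | Path) -> None:
    """Write a signal as 2-column CSV with a ``time_s,value`` header."""
    df = pd.DataFrame({"time_s": signal.times, "value": signal.values})
    df.to_csv(path, index=False, float_format="%.9g")


def read_signal_csv(path: str | Path) -> SampledSignal:
    """Read a 2-column (time_s, value) CSV written by :func:`write_signal_csv`.

    The sampling rate is recovered from the median time step; the grid must
    be uniform to within 1 ppm.
    """
    df = pd.read_csv(path)
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise ValueError(f"signal CSV {path} is missing column '{col}'")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"signal CSV {path} has fewer than 2 samples")
    dt = np.diff(t)
    step = float(np.median(dt))
    if step <= 0 or np.any(np.abs(dt - step) > 1e-6 * max(step, 1.0)):
        raise ValueError(f"signal CSV {path} is not uniformly sampled")
    return SampledSignal(df["value"].to_numpy(dtype=float), 1.0 / step, float(t[0]),
                         channel=Path(path).stem)
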