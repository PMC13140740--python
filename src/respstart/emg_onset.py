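"""EMG rectification and baseline-referenced burst-onset detection.

Reaction time is the interval between the cue and the first detectable
rise of EMG activity above baseline.  Detection follows the classic
3-SD rule: on the rectified signal, a short causal moving-average envelope
is compared against baseline mean + k * baseline SD (baseline taken from a
pre-cue window of the same envelope), and the onset is the first sample in
the post-cue search window where the envelope exceeds the threshold and
stays above it for a minimum sustained duration.

Because both the mean and the SD are measured from the baseline window,
the detected latency is invariant to positive rescaling of the signal.
The envelope exists because rectified EMG is a noise process whose
individual samples dip below any threshold; averaging over a few
milliseconds turns the variance step of a burst into a sustained level
shift without materially delaying it.  A degenerate baseline (SD = 0,
e.g. a noiseless recording) falls back to a threshold infinitesimally
above the baseline mean, so on noiseless step inputs the detector returns
the exact step sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signals import SampledSignal

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OnsetConfig:
    """Parameters of the threshold onset detector.

    baseline_window_s :
        (start, end) relative to the cue, both <= 0 (wholly pre-cue).
    threshold_k :
        Threshold in multiples of the baseline SD above the baseline mean.
    min_supra_ms :
        Minimum time the envelope must stay above threshold.
    search_window_ms :
        (min, max) admissible post-cue latencies.
    envelope_ms :
        Width of the causal moving-average envelope on the rectified signal.
    """

    baseline_window_s: tuple[float, float] = (-0.2, 0.0)
    threshold_k: float = 3.0
    min_supra_ms: float = 10.0
    search_window_ms: tuple[float, float] = (20.0, 600.0)
    envelope_ms: float = 5.0

    def __post_init__(self) -> None:
        b0, b1 = self.baseline_window_s
        if not (b0 < b1 <= 0.0):
            raise ValueError("baseline window must be wholly pre-cue (start < end <= 0)")
        if not self.threshold_k > 0:
            raise ValueError("threshold_k must be > 0")
        s0, s1 = self.search_window_ms
        if not (0.0 <= s0 < s1):
            raise ValueError("search window must satisfy 0 <= min < max")
        if self.min_supra_ms < 0 or self.envelope_ms < 0:
            raise ValueError("min_supra_ms and envelope_ms must be >= 0")


def rectify(signal: SampledSignal) -> SampledSignal:
    """Full-wave rectification: absolute value, same rate and length."""
    return SampledSignal(np.abs(signal.values), signal.rate_hz, signal.t0_s,
                         channel=signal.channel)


def _causal_envelope(values: np.ndarray, rate_hz: float, envelope_ms: float) -> np.ndarray:
    """Trailing moving average; output[i] averages samples (i-w, i]."""
    from scipy.ndimage import uniform_filter1d

    w = max(1, int(round(envelope_ms * rate_hz / 1000.0)))
    if w == 1:
        return np.asarray(values, dtype=float)
    # origin shifts the centred window so it trails the current sample
    return uniform_filter1d(np.asarray(values, dtype=float), size=w,
                            mode="nearest", origin=(w - 1) // 2)


def _first_sustained_crossing(env: np.ndarray, rate_hz: float, t0_s: float,
                              cue_time_s: float, threshold: float,
                              cfg: OnsetConfig) -> float | None:
    s0, s1 = cfg.search_window_ms
    i_lo = int(np.ceil((cue_time_s + s0 / 1000.0 - t0_s) * rate_hz - 1e-9))
    i_hi = int(np.floor((cue_time_s + s1 / 1000.0 - t0_s) * rate_hz + 1e-9))
    i_lo = max(0, i_lo)
    m = max(1, int(round(cfg.min_supra_ms * rate_hz / 1000.0)))
    i_hi = min(len(env) - m, i_hi)
    if i_hi < i_lo:
        return None
    above = env[i_lo:i_hi + m] > threshold
    c = np.concatenate([[0], np.cumsum(above)])
    sustained = (c[m:] - c[:-m]) == m  # all of [i, i+m) above threshold
    hits = np.nonzero(sustained[: i_hi - i_lo + 1])[0]
    if len(hits) == 0:
        return None
    i = i_lo + int(hits[0])
    return (t0_s + i / rate_hz - cue_time_s) * 1000.0


def detect_onset(rectified: SampledSignal, cue_time_s: float,
                 cfg: OnsetConfig = OnsetConfig()) -> float | None:
    """Burst-onset latency (ms after cue) on one rectified trace, or None.

    Raises if the baseline window falls outside the recorded span.
    """
    env = _causal_envelope(rectified.values, rectified.rate_hz, cfg.envelope_ms)
    return _detect_on_envelope(env, rectified.rate_hz, rectified.t0_s,
                               cue_time_s, cfg)[0]


def _detect_on_envelope(env: np.ndarray, rate_hz: float, t0_s: float,
                        cue_time_s: float, cfg: OnsetConfig):
    """Shared path for detect_onset / batch_onsets.

    Returns (latency_ms | None, threshold, baseline_mean, peak_ratio).
    """
    b0, b1 = cfg.baseline_window_s
    j0 = int(np.ceil((cue_time_s + b0 - t0_s) * rate_hz - 1e-9))
    j1 = int(np.floor((cue_time_s + b1 - t0_s) * rate_hz + 1e-9))
    if j0 < 0 or j1 > len(env) or j1 - j0 < 2:
        raise ValueError(
            f"baseline window [{cue_time_s + b0:.3f}, {cue_time_s + b1:.3f}] s "
            "falls outside the recorded span"
        )
    base = env[j0:j1]
    mu = float(base.mean())
    sd = float(base.std(ddof=0))
    if sd > 0:
        threshold = mu + cfg.threshold_k * sd
    else:
        # degenerate baseline: any detectable rise counts
        span = float(env.max() - mu)
        threshold = mu + (span * 1e-9 if span > 0 else 1e-300)
        logger.info("degenerate baseline (SD=0) at cue %.3f s; threshold set to "
                    "baseline mean + eps", cue_time_s)
    latency = _first_sustained_crossing(env, rate_hz, t0_s, cue_time_s,
                                        threshold, cfg)
    s1 = cfg.search_window_ms[1]
    i0 = max(0, int((cue_time_s - t0_s) * rate_hz))
    i1 = min(len(env), int((cue_time_s + s1 / 1000.0 - t0_s) * rate_hz) + 1)
    peak = float(env[i0:i1].max()) if i1 > i0 else np.nan
    ratio = peak / threshold if threshold > 0 else np.inf
    return latency, threshold, mu, ratio


def batch_onsets(signals: dict[str, SampledSignal], trials: pd.DataFrame,
                 cfg: OnsetConfig = OnsetConfig(),
                 rectified: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detect onsets for every trial on every muscle.

    Parameters
    ----------
    signals :
        Mapping muscle -> EMG trace (raw by default; set ``rectified`` if
        the traces are already rectified).
    trials :
        Trial table with a ``cue_time_s`` column.

    Returns
    -------
    (trials_out, qc)
        ``trials_out`` is a copy of ``trials`` with one ``rt_<muscle>_ms``
        column per muscle (NaN = no detectable onset).  ``qc`` is a
        per-trial, per-muscle review table (latency, peak/threshold ratio,
        detected flag) replacing the manual verification step of a
        semi-automated workflow.
    """
    out = trials.copy()
    qc_rows = []
    for muscle, sig in signals.items():
        rate = sig.rate_hz
        w = max(1, int(round(cfg.envelope_ms * rate / 1000.0)))
        col = np.full(len(out), np.nan)
        for row_i, cue in enumerate(out["cue_time_s"].to_numpy(dtype=float)):
            # envelope computed on a per-trial window: w warm-up samples
            # before the baseline, through the search window plus the
            # sustained-crossing horizon
            lo = cue + cfg.baseline_window_s[0] - (2 * w) / rate
            hi = (cue + (cfg.search_window_ms[1] + cfg.min_supra_ms) / 1000.0
                  + (2 * w) / rate)
            piece = sig.slice_seconds(lo, hi)
            vals = piece.values if rectified else np.abs(piece.values)
            env = _causal_envelope(vals, rate, cfg.envelope_ms)
            latency, thr, mu, ratio = _detect_on_envelope(
                env, rate, piece.t0_s, cue, cfg)
            col[row_i] = np.nan if latency is None else latency
            qc_rows.append(
                {"trial": row_i, "muscle": muscle, "cue_time_s": cue,
                 "latency_ms": col[row_i], "threshold": thr,
                 "peak_threshold_ratio": ratio,
                 "detected": latency is not None}
            )
        out[f"rt_{muscle}_ms"] = col
    return out, pd.DataFrame(qc_rows)


def no_onset_summary(trials: pd.DataFrame,
                     muscles: tuple[str, ...]) -> pd.DataFrame:
    """Count of undetected onsets per condition per muscle."""
    rows = []
    for cond, grp in trials.groupby("condition"):
        for m in muscles:
            col = f"rt_{m}_ms"
            rows.append({"condition": cond, "muscle": m,
                         "n_trials": len(grp),
                         "n_no_onset": int(grp[col].isna().sum())})
    return pd.DataFrame(rows)
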