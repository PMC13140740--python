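import numpy as np
import pandas as pd
import pytest

try:
    from hypothesis import settings

    settings.register_profile("suite", derandomize=True, max_examples=50,
                              deadline=None)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_trials(rng, n_participants=4, trials_per_condition=30,
                conditions=("VART", "VSRT"), muscles=("1DI",),
                baselines=None, phase_shift_ms=None, noise_sd=20.0):
    """Small hand-rolled trial table with uniform random phases.

    ``phase_shift_ms``: optional dict condition -> length-6 array added to
    the baseline as a deterministic per-phase offset (ground truth for
    modulation tests).
    """
    baselines = baselines or {c: 200.0 for c in conditions}
    rows = []
    for p in range(1, n_participants + 1):
        for cond in conditions:
            phases = rng.integers(1, 7, trials_per_condition)
            for x in phases:
                rt = baselines[cond] + noise_sd * rng.standard_normal()
                if phase_shift_ms and cond in phase_shift_ms:
                    rt += phase_shift_ms[cond][x - 1]
                row = {"participant": f"P{p:02d}", "block": 1,
                       "condition": cond, "cue_time_s": 0.0, "phase": int(x)}
                for m in muscles:
                    row[f"rt_{m}_ms"] = rt
                rows.append(row)
    df = pd.DataFrame(rows)
    df["phase"] = df["phase"].astype("Int64")
    return df


@pytest.fixture()
def trials_factory():
    return make_trials
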