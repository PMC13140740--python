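"""Synthetic StartReact datasets with full ground truth.

The generator emulates the statistical structure of a respiratory-phase x
StartReact experiment so that every downstream stage (breathing
segmentation, EMG onset detection, phase-resolved statistics, shuffle
nulls) can be tested against known truth:

* a randomized block schedule — per block each condition (VRT / VART /
  VSRT) appears a fixed number of times in seeded random order, with
  inter-trial intervals uniform on [12.5, 15.7] s (240 trials at the
  defaults: 20 trials x 3 conditions x 4 blocks);
* a quasi-periodic breathing temperature signal built from
  piecewise-cosine half-cycles (falling during inspiration, rising during
  expiration) with log-jittered cycle periods, so inspiration can occupy
  less than half the cycle as it does physiologically;
* per-trial reaction times RT = baseline(condition, muscle) +
  T_mod(phase) + Gaussian noise, where T_mod is the same two-harmonic
  mixture used by the analysis (offset k = 0); non-positive draws are
  resampled so the injected mean is exact;
* per-muscle EMG traces at 5 kHz: Gaussian baseline noise plus a
  higher-variance burst starting exactly at cue + RT.

One dataset seed drives everything through a documented seed-splitting
scheme: ``SeedSequence(seed)`` spawns one child per participant, and each
participant child spawns four independent substreams in the fixed order
(schedule, breathing, reaction times, EMG).

Default reaction-time baselines are the study-scale condition means
(VRT 280/254/223, VART 213/189/159, VSRT 162/151/126 ms for 1DI/FDS/BIC),
trial noise SD 45 ms, and the default phase modulation places a
reaction-time trough (first harmonic, amplitudes 14.4/9.3/8.6 ms in VSRT,
weaker in VART/VRT) at the inspiration-to-expiration transition x = 3.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import harmonic
from .resp_phase import PhaseSegmentation, RespCycle, label_times
from .signals import SampledSignal

SCHEMA_VERSION = "1"

CONDITIONS = ("VRT", "VART", "VSRT")
MUSCLES = ("1DI", "FDS", "BIC")

_TRANSITION_TROUGH_THETA1 = np.pi / 2 - 5 * np.pi / 6  # first harmonic extremal at x=3.5


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class ProtocolConfig:
    """Block/condition/timing structure of the trial schedule."""

    n_blocks: int = 4
    trials_per_condition_per_block: int = 20
    conditions: tuple[str, ...] = CONDITIONS
    iti_min_s: float = 12.5
    iti_max_s: float = 15.7

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.trials_per_condition_per_block < 1:
            raise ValueError("trials_per_condition_per_block must be >= 1")
        if len(self.conditions) < 1 or len(set(self.conditions)) != len(self.conditions):
            raise ValueError("conditions must be a non-empty set of distinct labels")
        if not self.iti_min_s < self.iti_max_s:
            raise ValueError("iti_min_s must be < iti_max_s")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * len(self.conditions) * self.trials_per_condition_per_block


@dataclass(frozen=True)
class BreathingConfig:
    """Quasi-periodic piecewise-cosine breathing signal parameters."""

    duration_s: float = 600.0
    sampling_rate_hz: float = 100.0
    mean_period_s: float = 4.0
    period_jitter_cv: float = 0.1
    inspiration_fraction: float = 0.4
    noise_sd: float = 0.02
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.duration_s < self.mean_period_s:
            raise ValueError("duration_s must cover at least one mean_period_s cycle")
        if self.sampling_rate_hz <= 2.0 / self.mean_period_s:
            raise ValueError("sampling_rate_hz must exceed 2 / mean_period_s")
        if not 0.0 < self.inspiration_fraction < 1.0:
            raise ValueError("inspiration_fraction must lie in (0, 1)")
        if self.period_jitter_cv < 0 or self.noise_sd < 0:
            raise ValueError("period_jitter_cv and noise_sd must be >= 0")


@dataclass(frozen=True)
class RtModel:
    """Per-condition, per-muscle reaction-time generative model (ms)."""

    baselines_ms: dict[str, dict[str, float]]
    modulation: dict[str, dict[str, harmonic.SinusoidFitParams]]
    noise_sd_ms: float = 45.0

    def __post_init__(self) -> None:
        for cond, per_muscle in self.baselines_ms.items():
            for muscle, b in per_muscle.items():
                if not b > 0:
                    raise ValueError(f"baseline for {cond}/{muscle} must be > 0")
        if self.noise_sd_ms < 0:
            raise ValueError("noise_sd_ms must be >= 0")

    def mean_rt_ms(self, condition: str, muscle: str, phase: int | np.ndarray):
        """Noise-free model mean: baseline + two-harmonic modulation (k = 0)."""
        base = self.baselines_ms[condition][muscle]
        mod = self.modulation.get(condition, {}).get(muscle)
        if mod is None:
            return base + np.zeros_like(np.asarray(phase, dtype=float))
        return base + harmonic.evaluate(replace(mod, k=0.0), phase)


def default_rt_model(noise_sd_ms: float = 45.0) -> RtModel:
    """Study-scale baselines with a VSRT reaction-time trough at x = 3.5."""
    baselines = {
        "VRT": {"1DI": 280.0, "FDS": 254.0, "BIC": 223.0},
        "VART": {"1DI": 213.0, "FDS": 189.0, "BIC": 159.0},
        "VSRT": {"1DI": 162.0, "FDS": 151.0, "BIC": 126.0},
    }
    amplitudes = {
        "VRT": {"1DI": 3.2, "FDS": 4.5, "BIC": 3.5},
        "VART": {"1DI": 6.4, "FDS": 1.7, "BIC": 2.2},
        "VSRT": {"1DI": 14.4, "FDS": 9.3, "BIC": 8.6},
    }
    # theta chosen so the first harmonic is *minimal* (RT trough = faster
    # responses) at the inspiration->expiration transition x = 3.5
    theta = _TRANSITION_TROUGH_THETA1 + np.pi
    theta = float(np.arctan2(np.sin(theta), np.cos(theta)))
    modulation = {
        cond: {m: harmonic.SinusoidFitParams(k=0.0, A1=a, theta1=theta, A2=0.0, theta2=0.0)
               for m, a in per.items()}
        for cond, per in amplitudes.items()
    }
    return RtModel(baselines_ms=baselines, modulation=modulation,
                   noise_sd_ms=noise_sd_ms)


def transition_trough_modulation(amplitude_ms: float) -> harmonic.SinusoidFitParams:
    """First harmonic with its minimum at the I3-E1 boundary (x = 3.5)."""
    theta = _TRANSITION_TROUGH_THETA1 + np.pi
    theta = float(np.arctan2(np.sin(theta), np.cos(theta)))
    return harmonic.SinusoidFitParams(k=0.0, A1=float(amplitude_ms), theta1=theta,
                                      A2=0.0, theta2=0.0)


def transition_peak_modulation(amplitude_ms: float) -> harmonic.SinusoidFitParams:
    """First harmonic with its maximum at the I3-E1 boundary (x = 3.5)."""
    return harmonic.SinusoidFitParams(k=0.0, A1=float(amplitude_ms),
                                      theta1=float(_TRANSITION_TROUGH_THETA1),
                                      A2=0.0, theta2=0.0)


@dataclass(frozen=True)
class EmgConfig:
    """EMG synthesis parameters (amplitudes in arbitrary units)."""

    rate_hz: float = 5000.0
    burst_amplitude: float = 10.0
    burst_duration_s: float = 0.15
    noise_sd: float = 1.0
    pre_s: float = 1.0   # signal span before the first cue
    post_s: float = 1.0  # span after the last burst

    def __post_init__(self) -> None:
        if self.burst_amplitude < 0:
            raise ValueError("burst_amplitude must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.rate_hz <= 0 or self.burst_duration_s <= 0:
            raise ValueError("rate_hz and burst_duration_s must be > 0")


# ---------------------------------------------------------------------------
# generators


def generate_schedule(cfg: ProtocolConfig, rng=None) -> pd.DataFrame:
    """Randomised trial schedule: per block, each condition appears exactly
    ``trials_per_condition_per_block`` times in shuffled order; successive
    cue gaps are uniform on [iti_min_s, iti_max_s]."""
    rng = _as_rng(rng)
    rows = []
    for block in range(1, cfg.n_blocks + 1):
        labels = np.repeat(np.asarray(cfg.conditions, dtype=object),
                           cfg.trials_per_condition_per_block)
        rng.shuffle(labels)
        rows.extend((block, c) for c in labels)
    itis = rng.uniform(cfg.iti_min_s, cfg.iti_max_s, size=len(rows))
    cue_times = np.cumsum(itis)
    return pd.DataFrame(
        {
            "block": [b for b, _ in rows],
            "condition": [c for _, c in rows],
            "cue_time_s": cue_times,
        }
    )


def generate_breathing(cfg: BreathingConfig, rng=None) -> tuple[SampledSignal, PhaseSegmentation]:
    """Piecewise-cosine breathing signal plus its ground-truth cycles.

    Within each cycle the noiseless waveform falls strictly from +amplitude
    at inspiration onset to -amplitude at expiration onset, then rises
    strictly back.  Only complete cycles inside ``duration_s`` are reported
    as ground truth; the waveform continues through a partial final cycle.
    """
    rng = _as_rng(rng)
    periods = []
    total = 0.0
    while total < cfg.duration_s + 2 * cfg.mean_period_s:
        p = cfg.mean_period_s * (1.0 + cfg.period_jitter_cv * rng.standard_normal())
        if p < 0.25 * cfg.mean_period_s:  # resample implausible draws
            continue
        periods.append(p)
        total += p
    periods = np.asarray(periods)
    insp = np.concatenate([[0.0], np.cumsum(periods)])[:-1]
    expi = insp + cfg.inspiration_fraction * periods
    ends = insp + periods

    t = np.arange(0.0, cfg.duration_s, 1.0 / cfg.sampling_rate_hz)
    ci = np.searchsorted(insp, t, side="right") - 1
    a, b, c = insp[ci], expi[ci], ends[ci]
    vals = np.where(
        t < b,
        np.cos(np.pi * (t - a) / (b - a)),
        -np.cos(np.pi * (t - b) / (c - b)),
    ) * cfg.amplitude
    if cfg.noise_sd > 0:
        vals = vals + cfg.noise_sd * rng.standard_normal(len(vals))
    signal = SampledSignal(vals, cfg.sampling_rate_hz, 0.0, channel="breathing")

    complete = ends <= cfg.duration_s + 1e-9
    cycles = [RespCycle(float(x), float(y), float(z))
              for x, y, z in zip(insp[complete], expi[complete], ends[complete])]
    if not cycles:
        raise ValueError("duration_s too short for a single complete cycle")
    truth = PhaseSegmentation(cycles, rate_hz=cfg.sampling_rate_hz,
                              duration_s=cfg.duration_s)
    return signal, truth


def generate_rts(schedule: pd.DataFrame, model: RtModel, rng=None,
                 muscles: tuple[str, ...] = MUSCLES,
                 phase_column: str = "phase") -> pd.DataFrame:
    """Ground-truth reaction times per trial per muscle.

    ``schedule`` must carry ``condition`` and a phase column with values in
    1..6; a missing phase raises an error identifying the trial.  Returns a
    copy with ``rt_<muscle>_ms`` columns appended.  Non-positive draws are
    resampled rather than truncated, keeping the injected mean exact.
    """
    rng = _as_rng(rng)
    if phase_column not in schedule.columns:
        raise ValueError(f"schedule is missing the '{phase_column}' column")
    phases = schedule[phase_column]
    bad = schedule.index[phases.isna()]
    if len(bad):
        raise ValueError(f"trial {bad[0]} has no respiratory phase")
    x = phases.to_numpy(dtype=float)
    if not np.all(np.isin(x, np.arange(1, 7))):
        bad = schedule.index[~np.isin(x, np.arange(1, 7))][0]
        raise ValueError(f"trial {bad} has phase outside 1..6")
    out = schedule.copy()
    for muscle in muscles:
        means = np.empty(len(out))
        for cond in out["condition"].unique():
            m = (out["condition"] == cond).to_numpy()
            means[m] = model.mean_rt_ms(str(cond), muscle, x[m])
        rts = means + model.noise_sd_ms * rng.standard_normal(len(out))
        bad = rts <= 0
        while np.any(bad):  # resample, not truncate
            rts[bad] = means[bad] + model.noise_sd_ms * rng.standard_normal(bad.sum())
            bad = rts <= 0
        out[f"rt_{muscle}_ms"] = rts
    return out


def synthesize_emg(schedule: pd.DataFrame, rts_ms: np.ndarray,
                   cfg: EmgConfig = EmgConfig(), rng=None,
                   channel: str = "emg") -> tuple[SampledSignal, np.ndarray]:
    """One muscle's EMG trace: baseline Gaussian noise plus per-trial bursts.

    Each burst is zero-mean Gaussian with SD ``burst_amplitude`` starting at
    cue + RT and lasting ``burst_duration_s`` (a rectangular envelope — the
    abrupt variance step is what the onset detector is specified against).

    Returns (signal, ground-truth onset sample indices).  Overlapping
    bursts from adjacent trials raise an error; the protocol's inter-trial
    intervals make overlap impossible at the defaults.
    """
    rng = _as_rng(rng)
    cues = schedule["cue_time_s"].to_numpy(dtype=float)
    rts_ms = np.asarray(rts_ms, dtype=float)
    if len(rts_ms) != len(cues):
        raise ValueError("rts_ms must have one entry per trial")
    onsets_s = cues + rts_ms / 1000.0
    order = np.argsort(onsets_s)
    if np.any(np.diff(onsets_s[order]) < cfg.burst_duration_s):
        raise ValueError("bursts from adjacent trials overlap")
    t0 = cues.min() - cfg.pre_s
    t_end = onsets_s.max() + cfg.burst_duration_s + cfg.post_s
    n = int(np.ceil((t_end - t0) * cfg.rate_hz))
    # float32 throughout: EMG traces are long (minutes at 5 kHz) and the
    # detector only needs ~3 significant figures of amplitude resolution
    vals = rng.standard_normal(n, dtype=np.float32)
    vals *= np.float32(cfg.noise_sd)
    onset_samples = np.rint((onsets_s - t0) * cfg.rate_hz).astype(int)
    n_burst = int(round(cfg.burst_duration_s * cfg.rate_hz))
    if cfg.burst_amplitude > 0:
        amp = np.float32(cfg.burst_amplitude)
        for i in onset_samples:
            j = min(n, i + n_burst)
            if i < n:
                vals[i:j] = amp * rng.standard_normal(j - i, dtype=np.float32)
    return SampledSignal(vals, cfg.rate_hz, t0, channel=channel), onset_samples


# ---------------------------------------------------------------------------
# whole-dataset generation


@dataclass(frozen=True)
class DatasetConfig:
    n_participants: int = 13
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    breathing: BreathingConfig = field(default_factory=BreathingConfig)
    rt_model: RtModel = field(default_factory=default_rt_model)
    emg: EmgConfig = field(default_factory=EmgConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")


@dataclass
class ParticipantData:
    participant: str
    trials: pd.DataFrame           # block, condition, cue_time_s, phase, rt_*_ms
    breathing: SampledSignal
    true_cycles: PhaseSegmentation
    emg_seeds: dict[str, np.random.SeedSequence]
    emg_cfg: EmgConfig

    def synthesize_emg(self, muscle: str) -> tuple[SampledSignal, np.ndarray]:
        """EMG trace for one muscle (generated on demand; deterministic)."""
        rng = np.random.default_rng(self.emg_seeds[muscle])
        return synthesize_emg(self.trials, self.trials[f"rt_{muscle}_ms"].to_numpy(),
                              self.emg_cfg, rng, channel=f"emg_{muscle}")


@dataclass
class SyntheticDataset:
    config: DatasetConfig
    participants: list[ParticipantData]

    @property
    def trials(self) -> pd.DataFrame:
        """All participants' trials with ground-truth phase and RT columns."""
        frames = []
        for p in self.participants:
            df = p.trials.copy()
            df.insert(0, "participant", p.participant)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def generate_dataset(cfg: DatasetConfig) -> SyntheticDataset:
    """Generate the full multi-participant dataset from one seed.

    Seed splitting: SeedSequence(seed) spawns one child per participant;
    each child spawns (schedule, breathing, rt, emg) substreams in that
    order, and the EMG substream spawns one grandchild per muscle.
    """
    root = np.random.SeedSequence(cfg.seed)
    participants = []
    for i, child in enumerate(root.spawn(cfg.n_participants), start=1):
        s_sched, s_breath, s_rt, s_emg = child.spawn(4)
        breathing_dur = _required_breathing_duration(cfg.protocol)
        bcfg = replace(cfg.breathing, duration_s=max(cfg.breathing.duration_s,
                                                     breathing_dur))
        schedule = generate_schedule(cfg.protocol, np.random.default_rng(s_sched))
        signal, truth = generate_breathing(bcfg, np.random.default_rng(s_breath))
        phases = label_times(truth, schedule["cue_time_s"].to_numpy())
        schedule = schedule.assign(
            phase=pd.array([int(x) if np.isfinite(x) else pd.NA for x in phases],
                           dtype="Int64")
        )
        # ground truth requires every cue inside a cycle; the breathing span
        # is sized to guarantee it
        if schedule["phase"].isna().any():
            raise RuntimeError("internal: cue outside generated breathing span")
        trials = generate_rts(schedule, cfg.rt_model, np.random.default_rng(s_rt))
        emg_seeds = dict(zip(MUSCLES, s_emg.spawn(len(MUSCLES))))
        participants.append(
            ParticipantData(
                participant=f"P{i:02d}", trials=trials, breathing=signal,
                true_cycles=truth, emg_seeds=emg_seeds, emg_cfg=cfg.emg,
            )
        )
    return SyntheticDataset(config=cfg, participants=participants)


def _required_breathing_duration(protocol: ProtocolConfig) -> float:
    """Breathing span guaranteed to cover the last cue plus margin."""
    return protocol.n_trials * protocol.iti_max_s + 30.0


# ---------------------------------------------------------------------------
# plain-text export


def write_dataset(ds: SyntheticDataset, out_dir: str | Path,
                  include_emg: bool = False) -> None:
    """Write trial table, breathing CSVs and ground-truth JSON to ``out_dir``."""
    from .signals import write_signal_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials = ds.trials
    cols = ["participant", "block", "condition", "cue_time_s"]
    trials[cols].to_csv(out / "trials.csv", index=False, float_format="%.6f")
    truth: dict = {"schema_version": SCHEMA_VERSION, "seed": ds.config.seed,
                   "participants": {}}
    for p in ds.participants:
        pdir = out / p.participant
        pdir.mkdir(exist_ok=True)
        write_signal_csv(p.breathing, pdir / "breathing.csv")
        if include_emg:
            for muscle in MUSCLES:
                sig, _ = p.synthesize_emg(muscle)
                write_signal_csv(sig, pdir / f"emg_{muscle}.csv")
        truth["participants"][p.participant] = {
            "cycles": p.true_cycles.to_frame().to_dict(orient="list"),
            "phase": [int(x) for x in p.trials["phase"]],
            "rt_ms": {m: [float(v) for v in p.trials[f"rt_{m}_ms"]] for m in MUSCLES},
        }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
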