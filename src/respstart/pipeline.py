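"""End-to-end orchestration: data in, phase-resolved report out.

A run proceeds through the same stages regardless of whether the input is
a synthetic dataset (simulate mode, full ground truth retained for QC) or
recorded CSVs: breathing segmentation -> respiratory phase per cue ->
EMG onset detection -> reaction-time table -> condition summaries,
StartReact effects, non-parametric test battery, two-harmonic fits,
shuffle-null landmark p-values and the focused transition contrasts.

Everything stochastic is derived from the configured seeds, so a report is
byte-reproducible from its configuration alone.  The shuffle nulls reuse
one B x 6 matrix of shuffled phase means per (condition, muscle) stratum;
all four landmark statistics project from the same matrix.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bootstrap, harmonic, rt_analysis
from ._version import __version__ as _pkg_version
from .emg_onset import OnsetConfig, batch_onsets, no_onset_summary
from .resp_phase import label_trials, segment_cycles
from .signals import read_signal_csv
from .synthetic import (
    MUSCLES,
    DatasetConfig,
    generate_dataset,
)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1"

TRIAL_COLUMNS = ("participant", "block", "condition", "cue_time_s")


@dataclass(frozen=True)
class PipelineConfig:
    """Single source of truth for a pipeline run.

    Exactly one of ``simulate`` / ``input_dir`` is active.  ``input_dir``
    must contain ``trials.csv`` plus one sub-directory per participant with
    ``breathing.csv`` and ``emg_<muscle>.csv`` files.
    """

    simulate: bool = True
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    input_dir: str | None = None
    onset: OnsetConfig = field(default_factory=OnsetConfig)
    min_half_cycle_s: float = 0.8
    smooth_window_s: float = 0.25
    refine_boundaries: bool = True
    b_reps: int = 10_000
    analysis_seed: int = 0
    landmarks: tuple[str, ...] = tuple(harmonic.LANDMARK_X)
    muscles: tuple[str, ...] = MUSCLES
    use_synthetic_emg: bool = True

    def __post_init__(self) -> None:
        if self.simulate == (self.input_dir is not None):
            raise ValueError("exactly one of simulate / input_dir must be active")
        if self.b_reps < 1:
            raise ValueError("b_reps must be >= 1")
        for lm in self.landmarks:
            if lm not in harmonic.LANDMARK_X:
                raise ValueError(f"unknown landmark '{lm}'")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        """Build a config from a plain (JSON-loadable) dict.

        Nested keys: ``dataset`` (n_participants, seed, plus ``protocol``,
        ``breathing``, ``emg`` sub-dicts and ``rt_model.noise_sd_ms``) and
        ``onset``; everything else maps to top-level fields.
        """
        from .synthetic import (BreathingConfig, EmgConfig, ProtocolConfig,
                                default_rt_model)

        d = dict(d)
        ds = dict(d.pop("dataset", {}))
        kwargs: dict = {}
        if ds:
            sub: dict = {}
            if "protocol" in ds:
                sub["protocol"] = ProtocolConfig(**ds.pop("protocol"))
            if "breathing" in ds:
                sub["breathing"] = BreathingConfig(**ds.pop("breathing"))
            if "emg" in ds:
                sub["emg"] = EmgConfig(**ds.pop("emg"))
            if "rt_model" in ds:
                rm = ds.pop("rt_model")
                sub["rt_model"] = default_rt_model(
                    noise_sd_ms=float(rm.get("noise_sd_ms", 45.0)))
            sub.update(ds)
            kwargs["dataset"] = DatasetConfig(**sub)
        if "onset" in d:
            on = dict(d.pop("onset"))
            for key in ("baseline_window_s", "search_window_ms"):
                if key in on:
                    on[key] = tuple(on[key])
            kwargs["onset"] = OnsetConfig(**on)
        if "landmarks" in d:
            d["landmarks"] = tuple(d["landmarks"])
        if "muscles" in d:
            d["muscles"] = tuple(d["muscles"])
        kwargs.update(d)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# input


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial table CSV.

    Requires the columns participant, block, condition, cue_time_s; unknown
    columns are preserved untouched.  Malformed numeric entries raise with
    the offending row number; an empty table is an explicit error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trial table not found: {path}")
    df = pd.read_csv(path)
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"trial table {path} is missing column '{col}'")
    if len(df) == 0:
        raise ValueError(f"trial table {path} is empty")
    for col in ("block", "cue_time_s"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad) or coerced.isna().any():
            row = int((bad if len(bad) else df.index[coerced.isna()])[0])
            raise ValueError(
                f"trial table {path}: malformed value in column '{col}', "
                f"row {row + 2}")  # +2: header line and 1-based numbering
        df[col] = coerced
    return df


# ---------------------------------------------------------------------------
# stage runners


def _assemble_simulated(cfg: PipelineConfig):
    ds = generate_dataset(cfg.dataset)
    frames = []
    qc = {"dropped_trials": {}, "phase_agreement": {}, "segmentation_warnings": {}}
    for p in ds.participants:
        seg = segment_cycles(p.breathing, cfg.min_half_cycle_s,
                             cfg.smooth_window_s, refine=cfg.refine_boundaries)
        if seg.warning:
            qc["segmentation_warnings"][p.participant] = seg.warning
        base_cols = ["block", "condition", "cue_time_s"]
        labelled, dropped = label_trials(seg, p.trials[base_cols])
        qc["dropped_trials"][p.participant] = dropped
        # phase agreement against generator truth (kept trials only)
        truth = p.trials.set_index("cue_time_s")["phase"]
        est = labelled.set_index("cue_time_s")["phase"]
        common = est.index.intersection(truth.index)
        agree = float((est.loc[common] == truth.loc[common]).mean())
        qc["phase_agreement"][p.participant] = agree
        if cfg.use_synthetic_emg:
            for muscle in cfg.muscles:
                sig, _ = p.synthesize_emg(muscle)
                labelled, _qc = batch_onsets({muscle: sig}, labelled, cfg.onset)
        else:  # carry ground-truth reaction times straight through
            rt_cols = [f"rt_{m}_ms" for m in cfg.muscles]
            labelled = labelled.merge(
                p.trials[["cue_time_s", *rt_cols]], on="cue_time_s", how="left")
        labelled.insert(0, "participant", p.participant)
        frames.append(labelled)
    trials = pd.concat(frames, ignore_index=True)
    return trials, qc


def _assemble_real(cfg: PipelineConfig):
    root = Path(cfg.input_dir)
    trials_all = read_trials(root / "trials.csv")
    frames = []
    qc = {"dropped_trials": {}, "segmentation_warnings": {}}
    for pid, part in trials_all.groupby("participant", sort=True):
        pdir = root / str(pid)
        bpath = pdir / "breathing.csv"
        if not bpath.exists():
            raise FileNotFoundError(f"missing breathing signal: {bpath}")
        seg = segment_cycles(read_signal_csv(bpath), cfg.min_half_cycle_s,
                             cfg.smooth_window_s, refine=cfg.refine_boundaries)
        if seg.warning:
            qc["segmentation_warnings"][str(pid)] = seg.warning
        labelled, dropped = label_trials(seg, part.reset_index(drop=True))
        qc["dropped_trials"][str(pid)] = dropped
        signals = {}
        for muscle in cfg.muscles:
            epath = pdir / f"emg_{muscle}.csv"
            if not epath.exists():
                raise FileNotFoundError(f"missing EMG signal: {epath}")
            signals[muscle] = read_signal_csv(epath)
        labelled, _qc = batch_onsets(signals, labelled, cfg.onset)
        frames.append(labelled)
    trials = pd.concat(frames, ignore_index=True)
    return trials, qc


# ---------------------------------------------------------------------------
# analysis


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def _phase_means_table(trials: pd.DataFrame, condition: str, muscle: str):
    col = rt_analysis.rt_column(muscle)
    sel = trials[(trials["condition"] == condition) & trials[col].notna()
                 & trials["phase"].notna()]
    means = sel.groupby("phase")[col].mean()
    return means.reindex(range(1, 7))


def _friedman_block(trials: pd.DataFrame, condition: str, muscle: str):
    """Friedman test across phases on per-participant phase means."""
    col = rt_analysis.rt_column(muscle)
    sel = trials[(trials["condition"] == condition) & trials[col].notna()
                 & trials["phase"].notna()]
    mat = sel.pivot_table(index="participant", columns="phase", values=col,
                          aggfunc="mean").reindex(columns=range(1, 7))
    complete = mat.dropna()
    excluded = sorted(set(mat.index) - set(complete.index))
    if len(complete) < 2:
        return {"condition": condition, "muscle": muscle, "statistic": None,
                "p": None, "n_participants": int(len(complete)),
                "excluded": [str(e) for e in excluded],
                "note": "fewer than 2 complete participants"}
    stat, p = rt_analysis.friedman_test(complete.to_numpy())
    return {"condition": condition, "muscle": muscle, "statistic": stat, "p": p,
            "n_participants": int(len(complete)),
            "excluded": [str(e) for e in excluded]}


def _landmark_tests(trials: pd.DataFrame, cfg: PipelineConfig) -> list[dict]:
    """All landmark shuffle tests, one null matrix per stratum."""
    root = np.random.SeedSequence(cfg.analysis_seed)
    results = []
    conditions = [c for c in rt_analysis.CONDITIONS
                  if (trials["condition"] == c).any()]
    # reaction-time statistics: one stratum per (condition, muscle)
    n_rt = len(conditions) * len(cfg.muscles)
    seeds = root.spawn(n_rt + len(cfg.muscles))
    si = 0
    null_cache: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for condition in conditions:
        for muscle in cfg.muscles:
            rng = np.random.default_rng(seeds[si]); si += 1
            try:
                rts, labels = bootstrap._stratum_arrays(trials, condition, muscle)
            except ValueError as err:
                results.append({"measure": "rt_mean", "condition": condition,
                                "muscle": muscle, "error": str(err)})
                continue
            obs6 = bootstrap.observed_phase_means(rts, labels)
            null6 = bootstrap.shuffled_phase_means(rts, labels, cfg.b_reps, rng)
            null_cache[(condition, muscle)] = (obs6, null6)
            for lm in cfg.landmarks:
                spec = bootstrap.StatisticSpec(measure="rt_mean", muscle=muscle,
                                               landmark=lm, condition=condition)
                proj = bootstrap._landmark_projection(lm)
                observed = float(obs6 @ proj)
                null = null6 @ proj
                count = int(np.sum(null >= observed) if spec.direction == "peak"
                            else np.sum(null <= observed))
                results.append({
                    "measure": "rt_mean", "condition": condition,
                    "muscle": muscle, "landmark": lm,
                    "direction": spec.direction, "observed_ms": observed,
                    "B": cfg.b_reps, "p": count / cfg.b_reps,
                })
    # StartReact-effect statistics: fresh shuffles per muscle
    for muscle in cfg.muscles:
        rng = np.random.default_rng(seeds[si]); si += 1
        try:
            rts_a, lab_a = bootstrap._stratum_arrays(trials, "VART", muscle)
            rts_s, lab_s = bootstrap._stratum_arrays(trials, "VSRT", muscle)
        except ValueError as err:
            results.append({"measure": "startreact_effect", "muscle": muscle,
                            "error": str(err)})
            continue
        obs6 = (bootstrap.observed_phase_means(rts_a, lab_a)
                - bootstrap.observed_phase_means(rts_s, lab_s))
        null6 = (bootstrap.shuffled_phase_means(rts_a, lab_a, cfg.b_reps, rng)
                 - bootstrap.shuffled_phase_means(rts_s, lab_s, cfg.b_reps, rng))
        for lm in cfg.landmarks:
            spec = bootstrap.StatisticSpec(measure="startreact_effect",
                                           muscle=muscle, landmark=lm)
            proj = bootstrap._landmark_projection(lm)
            observed = float(obs6 @ proj)
            null = null6 @ proj
            count = int(np.sum(null >= observed) if spec.direction == "peak"
                        else np.sum(null <= observed))
            results.append({
                "measure": "startreact_effect", "muscle": muscle,
                "landmark": lm, "direction": spec.direction,
                "observed_ms": observed, "B": cfg.b_reps,
                "p": count / cfg.b_reps,
            })
    return results


def _analyse(trials: pd.DataFrame, cfg: PipelineConfig) -> dict:
    conditions = [c for c in rt_analysis.CONDITIONS
                  if (trials["condition"] == c).any()]
    report: dict = {}

    summaries = []
    for condition in conditions:
        for muscle in cfg.muscles:
            s = rt_analysis.summarize(trials, condition, muscle)
            if s is None:
                continue
            summaries.append({"condition": condition, "muscle": muscle,
                              "n": s.n, "mean_ms": s.mean_ms, "sd_ms": s.sd_ms})
    report["condition_summaries"] = summaries

    normality = []
    for condition in conditions:
        for muscle in cfg.muscles:
            col = rt_analysis.rt_column(muscle)
            v = trials.loc[trials["condition"] == condition, col].dropna()
            if len(v) >= 3:
                normality.append({"condition": condition, "muscle": muscle,
                                  "n": int(len(v)),
                                  "p": rt_analysis.ks_normality(v.to_numpy())})
    report["ks_normality"] = normality

    comparisons = []
    for muscle in cfg.muscles:
        col = rt_analysis.rt_column(muscle)
        per_part = {
            c: trials[(trials["condition"] == c) & trials[col].notna()]
            .groupby("participant")[col].mean()
            for c in conditions
        }
        for i, a in enumerate(conditions):
            for b in conditions[i + 1:]:
                if len(per_part[a]) and len(per_part[b]):
                    comparisons.append({
                        "muscle": muscle, "a": a, "b": b,
                        "mean_a_ms": float(per_part[a].mean()),
                        "mean_b_ms": float(per_part[b].mean()),
                        "p": rt_analysis.mann_whitney_u(
                            per_part[a].to_numpy(), per_part[b].to_numpy()),
                    })
    report["condition_comparisons"] = comparisons

    if "VART" in conditions and "VSRT" in conditions:
        startreact = []
        for muscle in cfg.muscles:
            eff = rt_analysis.startreact_effect(trials, muscle)
            vals = np.array(list(eff.participant_effects.values()))
            entry = {"muscle": muscle, "effect_ms": eff.effect_ms,
                     "n_participants": len(vals),
                     "participant_mean_ms": float(vals.mean()) if len(vals) else None,
                     "participant_sd_ms": float(vals.std(ddof=1)) if len(vals) > 1 else None,
                     "p_vs_zero": rt_analysis.exact_wilcoxon_signed_rank(vals)
                     if len(vals) else None}
            per_phase = rt_analysis.startreact_effect(trials, muscle, per_phase=True)
            entry["per_phase_ms"] = {
                str(x): (None if e is None else e.effect_ms)
                for x, e in per_phase.items()}
            startreact.append(entry)
        report["startreact"] = startreact

        contrasts = []
        for muscle in cfg.muscles:
            for fn in (bootstrap.transition_vs_mid_test,
                       bootstrap.transition_ie_specific_test):
                try:
                    r = fn(trials, muscle)
                except ValueError as err:
                    contrasts.append({"muscle": muscle, "error": str(err)})
                    continue
                contrasts.append({"muscle": muscle, "kind": r.kind, "p": r.p,
                                  "n_participants": r.n_participants,
                                  "n_excluded": len(r.excluded)})
        report["phase_contrasts"] = contrasts

    report["friedman"] = [
        _friedman_block(trials, condition, muscle)
        for condition in conditions for muscle in cfg.muscles
    ]

    strength = []
    pairs = [(a, b) for i, a in enumerate(conditions) for b in conditions[i + 1:]]
    for muscle in cfg.muscles:
        per_cond = {c: rt_analysis.per_participant_strengths(trials, c, muscle)
                    for c in conditions}
        for a, b in pairs:
            sa, xa = per_cond[a]
            sb, xb = per_cond[b]
            if not (set(sa) & set(sb)):
                continue
            r = rt_analysis.compare_strength(sa, sb)
            strength.append({"muscle": muscle, "a": a, "b": b, "p": r.p,
                             "n": r.n, "mean_diff_ms": r.mean_diff,
                             "n_excluded": len(r.excluded) + len(xa) + len(xb)})
    report["strength_comparisons"] = strength

    fits = []
    for muscle in cfg.muscles:
        for condition in conditions:
            means = _phase_means_table(trials, condition, muscle)
            if means.isna().any():
                continue
            params = harmonic.fit_mixture(means.to_numpy())
            fits.append({
                "measure": "rt_mean", "condition": condition, "muscle": muscle,
                "phase_means_ms": [float(v) for v in means],
                "k_ms": params.k, "A1_ms": params.A1, "theta1_rad": params.theta1,
                "A2_ms": params.A2, "theta2_rad": params.theta2,
                "rss": params.rss,
                "modulation_amplitude_ms": harmonic.modulation_amplitude(params),
                "landmarks_ms": {lm: harmonic.landmark(params, lm).value
                                 for lm in cfg.landmarks},
            })
        if "VART" in conditions and "VSRT" in conditions:
            ma = _phase_means_table(trials, "VART", muscle)
            ms = _phase_means_table(trials, "VSRT", muscle)
            eff = ma - ms
            if not eff.isna().any():
                params = harmonic.fit_mixture(eff.to_numpy())
                fits.append({
                    "measure": "startreact_effect", "muscle": muscle,
                    "phase_means_ms": [float(v) for v in eff],
                    "k_ms": params.k, "A1_ms": params.A1,
                    "theta1_rad": params.theta1, "A2_ms": params.A2,
                    "theta2_rad": params.theta2, "rss": params.rss,
                    "modulation_amplitude_ms": harmonic.modulation_amplitude(params),
                    "landmarks_ms": {lm: harmonic.landmark(params, lm).value
                                     for lm in cfg.landmarks},
                })
    report["fits"] = fits

    report["landmark_tests"] = _landmark_tests(trials, cfg)
    return report


# ---------------------------------------------------------------------------
# entry points


def run(cfg: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline and return (optionally write) the report."""
    trials, qc = _assemble_simulated(cfg) if cfg.simulate else _assemble_real(cfg)
    for muscle in cfg.muscles:
        col = rt_analysis.rt_column(muscle)
        if col not in trials.columns:
            raise ValueError(f"trial table lacks reaction-time column '{col}'")
    qc["no_onset"] = no_onset_summary(trials, cfg.muscles).to_dict(orient="records")
    config_json = json.dumps(_jsonable(cfg), sort_keys=True)
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": _pkg_version,
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "n_trials": int(len(trials)),
        "qc": _jsonable(qc),
        "results": _jsonable(_analyse(trials, cfg)),
    }
    if out_dir is not None:
        write_report(report, trials, out_dir)
    return report


def write_report(report: dict, trials: pd.DataFrame | None,
                 out_dir: str | Path) -> None:
    """Write report.json plus CSV tables under ``out_dir``."""
    out = Path(out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    results = report.get("results", {})
    for name in ("condition_summaries", "condition_comparisons", "startreact",
                 "friedman", "strength_comparisons", "fits", "landmark_tests",
                 "phase_contrasts"):
        rows = results.get(name)
        if rows:
            pd.json_normalize(rows).to_csv(out / "tables" / f"{name}.csv",
                                           index=False)
    if trials is not None:
        trials.to_csv(out / "tables" / "trials.csv", index=False)
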