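"""Shuffle-based null distributions for phase-landmark statistics.

The significance of a peak or trough of the fitted two-harmonic curve is
assessed against simulated datasets obtained by randomly re-pairing
reaction times with respiratory phases: within each (condition, muscle)
stratum the multisets of phase labels and of reaction times are both
preserved and only their pairing is permuted, so the null targets phase
structure alone.  For each of B simulated datasets (default 10 000) the
six phase means are recomputed, the mixture refitted, and the landmark
extracted; the one-sided p-value is the proportion of simulated landmark
values that exceed the measured one (for peaks) or fall below it (for
troughs).

Because the fit is a closed-form linear projection, the whole null is two
matrix products: a B x 6 matrix of shuffled phase means (per stratum) and a
projection onto the landmark coordinate.

The module also provides the two focused phase contrasts on per-participant
StartReact effects: transition phases (I3, E1) against mid-phases (I2, E2)
as an unpaired rank-sum test on the pooled values, and a paired
within-participant version of the same contrast specific to the
inspiration-to-expiration transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import harmonic
from .rt_analysis import exact_wilcoxon_signed_rank, mann_whitney_u, rt_column


@dataclass(frozen=True)
class StatisticSpec:
    """What to measure before/after each shuffle.

    measure :
        "rt_mean" (phase means of one condition's reaction times) or
        "startreact_effect" (per-phase mean VART RT minus mean VSRT RT).
    condition :
        Required for "rt_mean"; ignored for the effect.
    muscle :
        Muscle whose reaction-time column is used.
    landmark :
        One of the :data:`respstart.harmonic.LANDMARK_X` kinds.
    direction :
        "peak" or "trough"; defaults follow the usage conventions — for the
        StartReact effect, peak at transitions / trough at mid-phases; for
        reaction times the reverse (a *shorter* RT marks enhancement).
    """

    measure: str
    muscle: str
    landmark: str
    condition: str | None = None
    direction: str | None = None

    def __post_init__(self) -> None:
        if self.measure not in ("rt_mean", "startreact_effect"):
            raise ValueError("measure must be 'rt_mean' or 'startreact_effect'")
        if self.measure == "rt_mean" and self.condition is None:
            raise ValueError("condition is required for measure 'rt_mean'")
        if self.landmark not in harmonic.LANDMARK_X:
            raise ValueError(f"unknown landmark '{self.landmark}'")
        if self.direction is None:
            at_transition = self.landmark.startswith("transition")
            if self.measure == "startreact_effect":
                d = "peak" if at_transition else "trough"
            else:
                d = "trough" if at_transition else "peak"
            object.__setattr__(self, "direction", d)
        if self.direction not in ("peak", "trough"):
            raise ValueError("direction must be 'peak' or 'trough'")


@dataclass
class NullDistribution:
    """Observed landmark value, its shuffle null and one-sided p-value."""

    observed: float
    B: int
    null_values: np.ndarray
    p: float
    direction: str
    seed: int | None = None
    add_one: bool = False

    def histogram(self, bins: int = 40) -> dict:
        counts, edges = np.histogram(self.null_values, bins=bins)
        return {"counts": counts.tolist(), "edges": edges.tolist()}


def shuffle_phase_labels(trials: pd.DataFrame, rng=None,
                         strata: tuple[str, ...] = ("condition",)) -> pd.DataFrame:
    """Permute the phase column within strata; everything else untouched.

    Phase-label and reaction-time multisets are preserved per stratum; only
    the pairing changes.  (Since each statistic concerns a single muscle,
    permuting the shared phase column within condition realises the
    within-(condition, muscle) shuffle for every muscle at once.)
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out = trials.copy()
    phases = out["phase"].to_numpy()
    for _, idx in out.groupby(list(strata)).indices.items():
        phases[idx] = phases[rng.permutation(idx)]
    out["phase"] = pd.array(phases, dtype=trials["phase"].dtype)
    return out


# ---------------------------------------------------------------------------
# vectorised null machinery


def _stratum_arrays(trials: pd.DataFrame, condition: str, muscle: str):
    col = rt_column(muscle)
    sel = trials[(trials["condition"] == condition) & trials[col].notna()
                 & trials["phase"].notna()]
    rts = sel[col].to_numpy(dtype=float)
    labels = sel["phase"].to_numpy(dtype=int)
    counts = np.bincount(labels, minlength=7)[1:7]
    if np.any(counts == 0):
        empty = int(np.argmin(counts)) + 1
        raise ValueError(
            f"phase {empty} has no {condition} trials for muscle {muscle}; "
            "landmark statistics need all six phases populated")
    return rts, labels


def observed_phase_means(rts: np.ndarray, labels: np.ndarray) -> np.ndarray:
    sums = np.bincount(labels, weights=rts, minlength=7)[1:7]
    counts = np.bincount(labels, minlength=7)[1:7]
    return sums / counts


def shuffled_phase_means(rts: np.ndarray, labels: np.ndarray, B: int,
                         rng: np.random.Generator) -> np.ndarray:
    """B x 6 matrix of phase means after B independent label permutations."""
    perm = rng.permuted(np.tile(rts, (B, 1)), axis=1)
    out = np.empty((B, 6))
    for x in range(1, 7):
        out[:, x - 1] = perm[:, labels == x].mean(axis=1)
    return out


def _landmark_projection(kind: str) -> np.ndarray:
    """Row vector v with landmark value = phase_means @ v (fit + evaluate)."""
    bx = harmonic.design_matrix(harmonic.LANDMARK_X[kind])
    return harmonic._PROJ.T @ bx


def landmark_pvalue(trials: pd.DataFrame, spec: StatisticSpec, B: int = 10_000,
                    seed: int | None = None, rng=None,
                    add_one: bool = False) -> NullDistribution:
    """Shuffle null and one-sided p-value for one landmark statistic.

    p = #(null >= observed) / B for peaks and #(null <= observed) / B for
    troughs, exactly as defined; ``add_one`` switches to (count+1)/(B+1),
    which avoids p = 0.  The observed value never depends on the seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    proj = _landmark_projection(spec.landmark)
    if spec.measure == "rt_mean":
        rts, labels = _stratum_arrays(trials, spec.condition, spec.muscle)
        observed = float(observed_phase_means(rts, labels) @ proj)
        null = shuffled_phase_means(rts, labels, B, rng) @ proj
    else:
        rts_a, lab_a = _stratum_arrays(trials, "VART", spec.muscle)
        rts_s, lab_s = _stratum_arrays(trials, "VSRT", spec.muscle)
        observed = float(
            (observed_phase_means(rts_a, lab_a)
             - observed_phase_means(rts_s, lab_s)) @ proj)
        null = (shuffled_phase_means(rts_a, lab_a, B, rng)
                - shuffled_phase_means(rts_s, lab_s, B, rng)) @ proj
    if spec.direction == "peak":
        count = int(np.sum(null >= observed))
    else:
        count = int(np.sum(null <= observed))
    p = (count + 1) / (B + 1) if add_one else count / B
    return NullDistribution(observed=observed, B=B, null_values=null, p=float(p),
                            direction=spec.direction, seed=seed, add_one=add_one)


# ---------------------------------------------------------------------------
# focused phase contrasts on per-participant StartReact effects


TRANSITION_PHASES = (3, 4)  # I3, E1
MID_PHASES = (2, 5)         # I2, E2


@dataclass(frozen=True)
class PhaseContrastResult:
    p: float
    muscle: str
    n_participants: int
    excluded: tuple[str, ...]
    transition_values: tuple[float, ...] = field(default=())
    mid_values: tuple[float, ...] = field(default=())
    kind: str = "transition_vs_mid"


def per_participant_phase_effects(trials: pd.DataFrame, muscle: str,
                                  phases) -> tuple[dict[str, dict[int, float]], list[str]]:
    """Per-participant StartReact effect (VART - VSRT mean RT) per phase.

    Participants lacking either condition in any requested phase cell are
    excluded and listed.
    """
    col = rt_column(muscle)
    sel = trials[trials[col].notna() & trials["phase"].notna()]
    effects: dict[str, dict[int, float]] = {}
    excluded: list[str] = []
    for pid, grp in sel.groupby("participant"):
        per_phase: dict[int, float] = {}
        ok = True
        for x in phases:
            a = grp[(grp["condition"] == "VART") & (grp["phase"] == x)][col]
            s = grp[(grp["condition"] == "VSRT") & (grp["phase"] == x)][col]
            if len(a) == 0 or len(s) == 0:
                ok = False
                break
            per_phase[int(x)] = float(a.mean() - s.mean())
        if ok:
            effects[str(pid)] = per_phase
        else:
            excluded.append(str(pid))
    return effects, excluded


def transition_vs_mid_test(trials: pd.DataFrame, muscle: str,
                           transition_phases=TRANSITION_PHASES,
                           mid_phases=MID_PHASES) -> PhaseContrastResult:
    """Rank-sum test: pooled per-participant effects at transition phases
    (I3, E1) against pooled effects at mid-phases (I2, E2)."""
    phases = tuple(transition_phases) + tuple(mid_phases)
    effects, excluded = per_participant_phase_effects(trials, muscle, phases)
    if not effects:
        raise ValueError("no participant has all required phase cells")
    trans = [e[x] for e in effects.values() for x in transition_phases]
    mid = [e[x] for e in effects.values() for x in mid_phases]
    p = mann_whitney_u(trans, mid)
    return PhaseContrastResult(p=p, muscle=muscle, n_participants=len(effects),
                               excluded=tuple(excluded),
                               transition_values=tuple(trans),
                               mid_values=tuple(mid), kind="transition_vs_mid")


def transition_ie_specific_test(trials: pd.DataFrame, muscle: str,
                                transition_phases=TRANSITION_PHASES,
                                mid_phases=MID_PHASES) -> PhaseContrastResult:
    """Paired within-participant contrast specific to the inspiration-to-
    expiration transition: signed-rank on per-participant differences
    mean(effect at I3, E1) - mean(effect at I2, E2)."""
    phases = tuple(transition_phases) + tuple(mid_phases)
    effects, excluded = per_participant_phase_effects(trials, muscle, phases)
    if not effects:
        raise ValueError("no participant has all required phase cells")
    diffs = np.array(
        [np.mean([e[x] for x in transition_phases])
         - np.mean([e[x] for x in mid_phases]) for e in effects.values()]
    )
    p = 1.0 if np.all(diffs == 0) else exact_wilcoxon_signed_rank(diffs)
    trans = [e[x] for e in effects.values() for x in transition_phases]
    mid = [e[x] for e in effects.values() for x in mid_phases]
    return PhaseContrastResult(p=p, muscle=muscle, n_participants=len(effects),
                               excluded=tuple(excluded),
                               transition_values=tuple(trans),
                               mid_values=tuple(mid), kind="transition_IE_specific")
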