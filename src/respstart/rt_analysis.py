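"""Condition-level reaction-time summaries and the non-parametric test battery.

The trial table convention used throughout the package is a pandas
DataFrame with (at least) the columns ``participant``, ``condition``
(VRT / VART / VSRT), ``phase`` (respiratory phase index 1..6, nullable) and
one reaction-time column per muscle named ``rt_<MUSCLE>_ms`` (e.g.
``rt_1DI_ms``); missing entries mean "no detectable onset".

Statistics follow the study's usage: Kolmogorov-Smirnov normality screen,
Mann-Whitney U for between-condition contrasts, one-sample Wilcoxon
signed-rank for the StartReact effect against zero, a Friedman test for
within-participant phase effects, and the SD of the six per-phase means as
the per-participant "modulation strength" compared between conditions with
a paired signed-rank test.

The signed-rank test is exact (full null distribution of the positive rank
sum, computed by dynamic programming on doubled average ranks, which remains
exact under tied |values|) up to n = 25, with a tie-corrected normal
approximation above.  The Friedman statistic is the tie-corrected rank form,
valid from k = 2 treatments.  All tests are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CONDITIONS = ("VRT", "VART", "VSRT")
MUSCLES = ("1DI", "FDS", "BIC")

EXACT_WILCOXON_MAX_N = 25
EXACT_MWU_MAX_N = 20


def rt_column(muscle: str) -> str:
    return f"rt_{muscle}_ms"


# ---------------------------------------------------------------------------
# summaries


@dataclass(frozen=True)
class ConditionSummary:
    condition: str
    muscle: str
    n: int
    mean_ms: float
    sd_ms: float
    participant_means: dict[str, float] = field(default_factory=dict)
    phase: int | None = None


@dataclass(frozen=True)
class StartReactEffect:
    """VART minus VSRT mean reaction time; positive = startle speeds the response."""

    muscle: str
    effect_ms: float
    n_vart: int
    n_vsrt: int
    participant_effects: dict[str, float] = field(default_factory=dict)
    phase: int | None = None


def _cell(trials: pd.DataFrame, condition: str, muscle: str,
          phase: int | None) -> pd.DataFrame:
    col = rt_column(muscle)
    sel = (trials["condition"] == condition) & trials[col].notna()
    if phase is not None:
        sel &= trials["phase"] == phase
    return trials.loc[sel, ["participant", col]]


def _summarize_cell(cell: pd.DataFrame, condition: str, muscle: str,
                    phase: int | None) -> ConditionSummary | None:
    col = cell.columns[-1]
    v = cell[col].to_numpy(dtype=float)
    if len(v) == 0:
        return None  # explicit empty marker, never zero
    sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    pm = cell.groupby("participant")[col].mean().to_dict()
    return ConditionSummary(condition=condition, muscle=muscle, n=len(v),
                            mean_ms=float(v.mean()), sd_ms=sd,
                            participant_means={str(k): float(x) for k, x in pm.items()},
                            phase=phase)


def summarize(trials: pd.DataFrame, condition: str, muscle: str,
              group_by_phase: bool = False):
    """Mean/SD reaction time for one condition x muscle cell.

    With ``group_by_phase`` a dict phase -> summary (or None for an empty
    phase cell) is returned; otherwise a single pooled summary (None if the
    cell is empty).  Per-participant means are included; weighted by trial
    counts they reproduce the pooled mean exactly.
    """
    if group_by_phase:
        return {x: _summarize_cell(_cell(trials, condition, muscle, x),
                                   condition, muscle, x)
                for x in range(1, 7)}
    return _summarize_cell(_cell(trials, condition, muscle, None), condition, muscle, None)


def _effect_cell(trials: pd.DataFrame, muscle: str, phase: int | None):
    a = _cell(trials, "VART", muscle, phase)
    b = _cell(trials, "VSRT", muscle, phase)
    if len(a) == 0 or len(b) == 0:
        return None
    col = rt_column(muscle)
    pa = a.groupby("participant")[col].mean()
    pb = b.groupby("participant")[col].mean()
    both = pa.index.intersection(pb.index)
    per_part = {str(p): float(pa[p] - pb[p]) for p in both}
    return StartReactEffect(
        muscle=muscle,
        effect_ms=float(a[col].mean() - b[col].mean()),
        n_vart=len(a), n_vsrt=len(b),
        participant_effects=per_part, phase=phase,
    )


def startreact_effect(trials: pd.DataFrame, muscle: str, per_phase: bool = False):
    """StartReact effect = mean(VART RT) - mean(VSRT RT), pooled or per phase.

    Per-phase results with a condition absent in that phase cell are None.
    """
    if per_phase:
        return {x: _effect_cell(trials, muscle, x) for x in range(1, 7)}
    eff = _effect_cell(trials, muscle, None)
    if eff is None:
        raise ValueError(f"both VART and VSRT trials required for muscle {muscle}")
    return eff


# ---------------------------------------------------------------------------
# tests


def _signed_rank_exact_p(w2: int, ranks2: np.ndarray) -> float:
    """Exact two-sided p for positive-rank sum, on doubled (integer) ranks.

    Enumerates the full sign-flip null via subset-sum counts: under H0 each
    of the 2^n sign assignments is equally likely and W = sum of ranks of
    the positive values.  Doubling average ranks makes them integers, so the
    distribution is exact also with tied |values|.  The distribution is
    symmetric about S/2; two-sided p = P(|W - S/2| >= |w - S/2|).
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    dev = np.abs(np.arange(total + 1) - total / 2.0)
    p = counts[dev >= abs(w2 - total / 2.0) - 1e-9].sum() / counts.sum()
    return float(min(1.0, p))


def exact_wilcoxon_signed_rank(values) -> float:
    """Two-sided one-sample Wilcoxon signed-rank p-value against zero median.

    Zeros are dropped (Wilcoxon convention).  Exact full enumeration of the
    sign-flip null for n <= 25 (tie-safe); tie-corrected normal
    approximation with continuity correction above.  All values zero (or an
    empty sample) gives p = 1 with a warning.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    v = v[v != 0.0]
    n = len(v)
    if n == 0:
        warnings.warn("signed-rank: all values are zero; p = 1", stacklevel=2)
        return 1.0
    ranks = stats.rankdata(np.abs(v))  # average ranks; may be half-integers
    w_pos = float(ranks[v > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        ranks2 = np.rint(2 * ranks).astype(int)
        return _signed_rank_exact_p(int(round(2 * w_pos)), ranks2)
    mu = n * (n + 1) / 4.0
    sigma = float(np.sqrt(np.sum(ranks**2) / 4.0))  # = tie-corrected variance
    if sigma == 0.0:
        return 1.0
    z = (abs(w_pos - mu) - 0.5) / sigma
    return float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))


def mann_whitney_u(a, b) -> float:
    """Two-sided Mann-Whitney U (Wilcoxon rank-sum) p-value.

    Exact when m + n <= 20 and there are no ties across the pooled sample;
    otherwise the tie-corrected normal approximation (no continuity
    correction, so identical samples give exactly p = 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if no_ties and len(pooled) <= EXACT_MWU_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=False)
    p = float(res.pvalue)
    if not np.isfinite(p):  # zero-variance degenerate case (all values equal)
        p = 1.0
    return min(1.0, p)


def friedman_test(matrix) -> tuple[float, float]:
    """Friedman rank test on a participants x treatments matrix.

    Tie-corrected chi-squared form with average ranks, valid from 2
    treatments; missing cells are an error (no imputation).

    Returns (statistic, p) with a chi-squared(k-1) reference distribution.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("matrix must be 2-D with >= 2 rows and >= 2 columns")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix contains missing/non-finite cells")
    n, k = m.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, m)
    col_sums = ranks.sum(axis=0)
    numer = (k - 1) * float(np.sum((col_sums - n * (k + 1) / 2.0) ** 2))
    denom = float(np.sum(ranks**2)) - n * k * (k + 1) ** 2 / 4.0
    if denom <= 0.0:  # all rows completely tied
        return 0.0, 1.0
    statistic = numer / denom
    return statistic, float(stats.chi2.sf(statistic, k - 1))


def ks_normality(values) -> float:
    """One-sample Kolmogorov-Smirnov p-value against a normal reference.

    The sample is standardised by its own mean and SD and compared against
    the standard normal CDF (no Lilliefors small-sample correction, matching
    the plain KS screen used to decide for non-parametric tests).
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 values")
    sd = np.std(v, ddof=1)
    if sd == 0:
        return 0.0  # a point mass is maximally non-normal
    z = (v - v.mean()) / sd
    return float(stats.kstest(z, "norm").pvalue)


# ---------------------------------------------------------------------------
# modulation strength


def modulation_strength(phase_means) -> float:
    """SD across the six per-phase mean reaction times (ms)."""
    v = np.asarray(phase_means, dtype=float)
    if v.shape != (6,) or not np.all(np.isfinite(v)):
        raise ValueError("phase_means must be 6 finite values")
    return float(np.std(v, ddof=1))


def per_participant_strengths(trials: pd.DataFrame, condition: str,
                              muscle: str) -> tuple[dict[str, float], list[str]]:
    """Per-participant modulation strength for one condition x muscle.

    Returns (strengths, excluded): participants missing any of the six phase
    cells are excluded and listed.
    """
    col = rt_column(muscle)
    sel = trials[(trials["condition"] == condition) & trials[col].notna()
                 & trials["phase"].notna()]
    strengths: dict[str, float] = {}
    excluded: list[str] = []
    for pid, grp in sel.groupby("participant"):
        means = grp.groupby("phase")[col].mean()
        if len(means) < 6:
            excluded.append(str(pid))
            continue
        strengths[str(pid)] = modulation_strength(means.sort_index().to_numpy())
    return strengths, excluded


@dataclass(frozen=True)
class StrengthComparison:
    p: float
    n: int
    mean_diff: float  # mean(strength A - strength B) over shared participants
    excluded: tuple[str, ...]


def compare_strength(strengths_a: dict[str, float],
                     strengths_b: dict[str, float]) -> StrengthComparison:
    """Paired signed-rank comparison of per-participant modulation strengths.

    Participants present in only one condition are excluded and reported.
    """
    shared = sorted(set(strengths_a) & set(strengths_b))
    if not shared:
        raise ValueError("no participants shared between the two conditions")
    excluded = tuple(sorted(set(strengths_a) ^ set(strengths_b)))
    diffs = np.array([strengths_a[p] - strengths_b[p] for p in shared])
    if np.all(diffs == 0):
        p = 1.0
    else:
        p = exact_wilcoxon_signed_rank(diffs)
    return StrengthComparison(p=p, n=len(shared), mean_diff=float(diffs.mean()),
                              excluded=excluded)
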