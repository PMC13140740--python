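"""Summaries and the non-parametric test battery, with enumeration oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from respstart import rt_analysis as rta


# ---------------------------------------------------------------------------
# brute-force oracles


def wilcoxon_brute_force(values):
    """Two-sided signed-rank p by enumerating all 2^n sign assignments."""
    v = np.asarray(values, dtype=float)
    v = v[v != 0]
    n = len(v)
    ranks = stats.rankdata(np.abs(v))
    w_obs = ranks[v > 0].sum()
    mu = ranks.sum() / 2.0
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / 2**n


def mannwhitney_brute_force(a, b):
    """Two-sided rank-sum p by enumerating all C(m+n, m) group labelings."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    m = len(a)
    mu = m * (len(pooled) + 1) / 2.0
    r_obs = ranks[:m].sum()
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), m):
        r = ranks[list(idx)].sum()
        total += 1
        if abs(r - mu) >= abs(r_obs - mu) - 1e-9:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


class TestWilcoxon:
    def test_thirteen_positive_values_rounds_to_printed_p(self, rng):
        """13 same-sign differences give the extreme two-sided tail 2/2^13."""
        v = np.abs(rng.normal(51, 38, 13)) + 0.5
        p = rta.exact_wilcoxon_signed_rank(v)
        assert p == pytest.approx(2 / 2**13)
        assert round(p, 4) == 0.0002

    def test_five_positive_values_analytic(self):
        assert rta.exact_wilcoxon_signed_rank([3, 1, 4, 1.5, 9]) == pytest.approx(2 / 32)

    def test_all_zero_values_warns_p_one(self):
        with pytest.warns(UserWarning, match="all values are zero"):
            assert rta.exact_wilcoxon_signed_rank([0.0, 0.0]) == 1.0

    def test_matches_brute_force_enumeration(self, rng):
        for n in range(2, 9):
            for _ in range(10):
                v = rng.normal(0.3, 1.0, n)
                assert rta.exact_wilcoxon_signed_rank(v) == pytest.approx(
                    wilcoxon_brute_force(v)), f"n={n}, v={v}"

    def test_matches_brute_force_with_tied_magnitudes(self, rng):
        for _ in range(20):
            mags = rng.integers(1, 4, 7).astype(float)  # many tied |values|
            signs = rng.choice([-1.0, 1.0], 7)
            v = mags * signs
            assert rta.exact_wilcoxon_signed_rank(v) == pytest.approx(
                wilcoxon_brute_force(v)), v

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(20):
            v = rng.normal(0.5, 1.0, 12)
            expected = stats.wilcoxon(v, alternative="two-sided",
                                      method="exact").pvalue
            assert rta.exact_wilcoxon_signed_rank(v) == pytest.approx(expected)

    def test_large_sample_approximation_is_sane(self, rng):
        v = rng.normal(0.8, 1.0, 60)
        p = rta.exact_wilcoxon_signed_rank(v)
        expected = stats.wilcoxon(v, alternative="two-sided",
                                  method="approx", correction=True).pvalue
        assert p == pytest.approx(expected, rel=0.05)
        assert p < 0.01  # clear shift must be detected

    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=8))
    def test_p_in_unit_interval(self, values):
        if all(v == 0 for v in values):
            with pytest.warns(UserWarning):
                assert rta.exact_wilcoxon_signed_rank(values) == 1.0
        else:
            assert 0.0 < rta.exact_wilcoxon_signed_rank(values) <= 1.0


# ---------------------------------------------------------------------------
# Mann-Whitney


class TestMannWhitney:
    def test_disjoint_small_groups_analytic(self):
        # most extreme split of 6 values: p = 2/C(6,3) = 0.1
        assert rta.mann_whitney_u([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        assert rta.mann_whitney_u([1, 2, 3], [1, 2, 3]) == 1.0
        assert rta.mann_whitney_u([5.0] * 4, [5.0] * 6) == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rta.mann_whitney_u([], [1.0])

    def test_matches_brute_force_enumeration(self, rng):
        for m, n in [(2, 3), (3, 3), (4, 4), (3, 5)]:
            for _ in range(8):
                a = rng.normal(0, 1, m)
                b = rng.normal(0.5, 1, n)
                assert rta.mann_whitney_u(a, b) == pytest.approx(
                    mannwhitney_brute_force(a, b))


# ---------------------------------------------------------------------------
# Friedman


class TestFriedman:
    def test_identical_columns_statistic_zero(self):
        stat, p = rta.friedman_test(np.tile([[5.0, 5.0, 5.0]], (4, 1)))
        assert stat == 0.0 and p == 1.0

    def test_two_participants_three_phases_same_order(self):
        stat, p = rta.friedman_test([[1, 2, 3], [10, 20, 30]])
        assert stat == pytest.approx(4.0)
        assert p == pytest.approx(float(stats.chi2.sf(4.0, 2)))

    def test_column_permutation_invariance(self, rng):
        m = rng.normal(0, 1, (6, 4))
        stat, _ = rta.friedman_test(m)
        stat_perm, _ = rta.friedman_test(m[:, [2, 0, 3, 1]])
        assert stat == pytest.approx(stat_perm)

    def test_matches_scipy_for_three_plus_columns(self, rng):
        for _ in range(10):
            m = rng.normal(0, 1, (8, 5))
            stat, p = rta.friedman_test(m)
            ref = stats.friedmanchisquare(*(m[:, j] for j in range(5)))
            assert stat == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_missing_cells_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            rta.friedman_test([[1, np.nan, 3], [4, 5, 6]])
        with pytest.raises(ValueError):
            rta.friedman_test([[1, 2, 3]])  # single row


# ---------------------------------------------------------------------------
# KS normality


class TestKsNormality:
    def test_uniform_sample_rejected(self, rng):
        assert rta.ks_normality(rng.uniform(0, 1, 2000)) < 0.05

    def test_normal_quantiles_accepted(self):
        q = stats.norm.ppf(np.linspace(0.01, 0.99, 99))
        assert rta.ks_normality(q) > 0.5

    def test_deterministic(self, rng):
        v = rng.normal(0, 1, 50)
        assert rta.ks_normality(v) == rta.ks_normality(v.copy())


# ---------------------------------------------------------------------------
# summaries and effects


class TestSummaries:
    def test_single_trial_mean_and_zero_sd(self):
        df = pd.DataFrame({"participant": ["P1"], "condition": ["VSRT"],
                           "phase": pd.array([2], dtype="Int64"),
                           "rt_1DI_ms": [200.0]})
        s = rta.summarize(df, "VSRT", "1DI")
        assert s.n == 1 and s.mean_ms == 200.0 and s.sd_ms == 0.0

    def test_empty_cell_is_explicit_marker(self, trials_factory, rng):
        df = trials_factory(rng)
        assert rta.summarize(df, "VRT", "1DI") is None

    def test_pooled_mean_equals_count_weighted_phase_means(self, trials_factory, rng):
        df = trials_factory(rng)
        pooled = rta.summarize(df, "VSRT", "1DI")
        by_phase = rta.summarize(df, "VSRT", "1DI", group_by_phase=True)
        num = den = 0.0
        for s in by_phase.values():
            if s is not None:
                num += s.mean_ms * s.n
                den += s.n
        assert pooled.mean_ms == pytest.approx(num / den)
        assert pooled.n == den

    def test_trial_order_invariance(self, trials_factory, rng):
        df = trials_factory(rng)
        shuffled = df.sample(frac=1.0, random_state=7).reset_index(drop=True)
        a = rta.summarize(df, "VART", "1DI")
        b = rta.summarize(shuffled, "VART", "1DI")
        assert a.mean_ms == pytest.approx(b.mean_ms)
        assert a.sd_ms == pytest.approx(b.sd_ms)

    def test_participant_means_weighted_average_to_pooled(self, trials_factory, rng):
        df = trials_factory(rng)
        s = rta.summarize(df, "VART", "1DI")
        col = df[(df["condition"] == "VART")]
        weights = col.groupby("participant")["rt_1DI_ms"].count()
        weighted = sum(s.participant_means[p] * weights[p] for p in weights.index)
        assert weighted / weights.sum() == pytest.approx(s.mean_ms)


class TestStartReactEffect:
    def test_documented_means(self):
        rows = []
        for rt, cond in [(213.0, "VART"), (162.0, "VSRT")]:
            for i in range(5):
                rows.append({"participant": "P1", "condition": cond,
                             "phase": pd.NA, "rt_1DI_ms": rt})
        df = pd.DataFrame(rows)
        df["phase"] = pd.array([pd.NA] * len(df), dtype="Int64")
        eff = rta.startreact_effect(df, "1DI")
        assert eff.effect_ms == pytest.approx(51.0)

    def test_identical_distributions_zero_effect(self, trials_factory, rng):
        df = trials_factory(rng, baselines={"VART": 200.0, "VSRT": 200.0},
                            noise_sd=0.0)
        assert rta.startreact_effect(df, "1DI").effect_ms == pytest.approx(0.0)

    def test_injected_effect_recovered_within_three_se(self, trials_factory, rng):
        sd, n_per = 20.0, 120
        df = trials_factory(rng, n_participants=4, trials_per_condition=n_per,
                            baselines={"VART": 210.0, "VSRT": 160.0},
                            noise_sd=sd)
        eff = rta.startreact_effect(df, "1DI")
        se = sd * np.sqrt(2 / (4 * n_per))
        assert abs(eff.effect_ms - 50.0) < 3 * se

    def test_per_phase_missing_condition_is_none(self):
        df = pd.DataFrame({
            "participant": ["P1", "P1"], "condition": ["VART", "VSRT"],
            "phase": pd.array([1, 2], dtype="Int64"),
            "rt_1DI_ms": [200.0, 150.0]})
        per_phase = rta.startreact_effect(df, "1DI", per_phase=True)
        assert per_phase[1] is None and per_phase[3] is None


class TestModulationStrength:
    def test_constant_phase_means_zero_strength(self):
        assert rta.modulation_strength([180.0] * 6) == 0.0

    def test_identical_strengths_p_one(self):
        s = {"P1": 3.0, "P2": 5.0, "P3": 1.0}
        assert rta.compare_strength(s, dict(s)).p == 1.0

    def test_unshared_participants_excluded_and_reported(self):
        a = {"P1": 3.0, "P2": 5.0, "P3": 6.0}
        b = {"P1": 1.0, "P2": 2.0, "P4": 9.0}
        r = rta.compare_strength(a, b)
        assert r.n == 2 and set(r.excluded) == {"P3", "P4"}

    def test_per_participant_strengths_excludes_incomplete(self, trials_factory, rng):
        df = trials_factory(rng, n_participants=3, trials_per_condition=60)
        # knock out phase 4 for one participant
        mask = (df["participant"] == "P01") & (df["condition"] == "VSRT") \
            & (df["phase"] == 4)
        df = df[~mask]
        strengths, excluded = rta.per_participant_strengths(df, "VSRT", "1DI")
        assert "P01" in excluded
        assert set(strengths) == {"P02", "P03"}
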