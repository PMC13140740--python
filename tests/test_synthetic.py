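"""Generator contracts: schedule structure, breathing shape, RT model, EMG."""

import numpy as np
import pandas as pd
import pytest

import respstart as rs
from respstart import harmonic
from respstart.synthetic import EmgConfig, _required_breathing_duration


class TestSchedule:
    def test_default_protocol_counts(self):
        sched = rs.generate_schedule(rs.ProtocolConfig(), 0)
        assert len(sched) == 240
        assert sched["condition"].value_counts().eq(80).all()
        per_block = sched.groupby(["block", "condition"]).size()
        assert per_block.eq(20).all()

    def test_itis_within_bounds(self):
        cfg = rs.ProtocolConfig()
        sched = rs.generate_schedule(cfg, 3)
        gaps = np.diff(np.concatenate([[0.0], sched["cue_time_s"].to_numpy()]))
        assert np.all(gaps >= cfg.iti_min_s) and np.all(gaps <= cfg.iti_max_s)

    def test_seeded_determinism(self):
        a = rs.generate_schedule(rs.ProtocolConfig(), 11)
        b = rs.generate_schedule(rs.ProtocolConfig(), 11)
        pd.testing.assert_frame_equal(a, b)

    def test_minimal_protocol(self):
        sched = rs.generate_schedule(
            rs.ProtocolConfig(n_blocks=1, trials_per_condition_per_block=1), 0)
        assert len(sched) == 3
        assert set(sched["condition"]) == {"VRT", "VART", "VSRT"}

    @pytest.mark.parametrize("field,value", [
        ("n_blocks", 0),
        ("trials_per_condition_per_block", 0),
        ("iti_min_s", 20.0),  # >= iti_max
    ])
    def test_invalid_config_names_field(self, field, value):
        with pytest.raises(ValueError, match=field.split("_")[0]):
            rs.ProtocolConfig(**{field: value})


class TestBreathing:
    def test_jitter_free_cycle_count(self):
        sig, truth = rs.generate_breathing(
            rs.BreathingConfig(duration_s=60, period_jitter_cv=0.0,
                               noise_sd=0.0), 0)
        assert len(truth) == 15
        lengths = [c.end_s - c.inspiration_onset_s for c in truth.cycles]
        assert np.allclose(lengths, 4.0)

    def test_empirical_period_cv_in_band(self):
        _, truth = rs.generate_breathing(
            rs.BreathingConfig(duration_s=600, period_jitter_cv=0.1), 5)
        periods = np.array([c.end_s - c.inspiration_onset_s for c in truth.cycles])
        cv = periods.std() / periods.mean()
        assert 0.05 <= cv <= 0.15

    def test_noiseless_waveform_monotone_within_half_cycles(self):
        cfg = rs.BreathingConfig(duration_s=40, period_jitter_cv=0.05,
                                 noise_sd=0.0)
        sig, truth = rs.generate_breathing(cfg, 2)
        t = sig.times
        for c in truth.cycles[:5]:
            insp = sig.values[(t >= c.inspiration_onset_s) & (t < c.expiration_onset_s)]
            expi = sig.values[(t >= c.expiration_onset_s) & (t < c.end_s)]
            assert np.all(np.diff(insp) < 0)
            assert np.all(np.diff(expi) > 0)

    def test_expiration_onset_is_cycle_minimum_without_noise(self):
        sig, truth = rs.generate_breathing(
            rs.BreathingConfig(duration_s=40, noise_sd=0.0), 3)
        t = sig.times
        for c in truth.cycles[:5]:
            in_cycle = (t >= c.inspiration_onset_s) & (t < c.end_s)
            t_min = t[in_cycle][np.argmin(sig.values[in_cycle])]
            # sampled minimum sits within one sample of the true onset
            assert abs(t_min - c.expiration_onset_s) <= 1.5 / sig.rate_hz

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            rs.BreathingConfig(duration_s=2.0, mean_period_s=4.0)

    def test_inspiration_fraction_validated(self):
        with pytest.raises(ValueError, match="inspiration_fraction"):
            rs.BreathingConfig(inspiration_fraction=1.2)


class TestReactionTimes:
    def _schedule_with_phases(self, rng, n=60):
        sched = rs.generate_schedule(
            rs.ProtocolConfig(n_blocks=1, trials_per_condition_per_block=n // 3), rng)
        sched["phase"] = pd.array(rng.integers(1, 7, len(sched)), dtype="Int64")
        return sched

    def test_zero_noise_zero_modulation_forces_baseline(self, rng):
        sched = self._schedule_with_phases(rng)
        model = rs.RtModel(
            baselines_ms={"VRT": {"1DI": 280.0}, "VART": {"1DI": 213.0},
                          "VSRT": {"1DI": 162.0}},
            modulation={}, noise_sd_ms=0.0)
        out = rs.generate_rts(sched, model, rng, muscles=("1DI",))
        vsrt = out[out["condition"] == "VSRT"]["rt_1DI_ms"]
        assert np.allclose(vsrt, 162.0)

    def test_first_harmonic_symmetry_between_opposite_phases(self, rng):
        """A1=10 maximal at x=2 gives RT(x=2) - RT(x=5) = 20 ms at zero noise."""
        theta = np.pi / 2 - harmonic.OMEGA  # sin(omega*(2-1)+theta) = 1
        mod = harmonic.SinusoidFitParams(k=0, A1=10.0, theta1=theta, A2=0, theta2=0)
        sched = pd.DataFrame({"condition": ["VSRT"] * 2,
                              "phase": pd.array([2, 5], dtype="Int64")})
        model = rs.RtModel(baselines_ms={"VSRT": {"1DI": 162.0}},
                           modulation={"VSRT": {"1DI": mod}}, noise_sd_ms=0.0)
        out = rs.generate_rts(sched, model, rng, muscles=("1DI",))
        assert out["rt_1DI_ms"].iloc[0] - out["rt_1DI_ms"].iloc[1] == pytest.approx(20.0)

    def test_sample_mean_matches_model_mean(self, rng):
        sched = pd.DataFrame({"condition": ["VSRT"] * 10_000,
                              "phase": pd.array([3] * 10_000, dtype="Int64")})
        model = rs.default_rt_model(noise_sd_ms=45.0)
        out = rs.generate_rts(sched, model, rng, muscles=("1DI",))
        expected = model.mean_rt_ms("VSRT", "1DI", 3)
        assert abs(out["rt_1DI_ms"].mean() - expected) < 3 * 45 / np.sqrt(10_000)

    def test_missing_phase_identifies_trial(self, rng):
        sched = pd.DataFrame({"condition": ["VSRT", "VSRT"],
                              "phase": pd.array([2, pd.NA], dtype="Int64")})
        with pytest.raises(ValueError, match="trial 1"):
            rs.generate_rts(sched, rs.default_rt_model(), rng)

    def test_all_rts_positive_via_resampling(self, rng):
        sched = pd.DataFrame({"condition": ["VSRT"] * 3000,
                              "phase": pd.array([1] * 3000, dtype="Int64")})
        model = rs.RtModel(baselines_ms={"VSRT": {"1DI": 30.0}},
                           modulation={}, noise_sd_ms=60.0)
        out = rs.generate_rts(sched, model, rng, muscles=("1DI",))
        assert (out["rt_1DI_ms"] > 0).all()

    def test_roundtrip_fit_recovers_injected_modulation(self):
        """Noise-free phase means refitted by the mixture reproduce the
        injected amplitudes/phases to 1e-9 relative accuracy."""
        mod = harmonic.SinusoidFitParams(k=0.0, A1=12.0, theta1=0.8,
                                         A2=5.0, theta2=-2.0)
        model = rs.RtModel(baselines_ms={"VSRT": {"1DI": 162.0}},
                           modulation={"VSRT": {"1DI": mod}}, noise_sd_ms=0.0)
        sched = pd.DataFrame({"condition": ["VSRT"] * 6,
                              "phase": pd.array(range(1, 7), dtype="Int64")})
        out = rs.generate_rts(sched, model, np.random.default_rng(0),
                              muscles=("1DI",))
        fit = harmonic.fit_mixture(out["rt_1DI_ms"].to_numpy())
        assert fit.k == pytest.approx(162.0, rel=1e-9)
        assert fit.A1 == pytest.approx(12.0, rel=1e-9)
        assert fit.theta1 == pytest.approx(0.8, rel=1e-9)
        assert fit.A2 == pytest.approx(5.0, rel=1e-9)
        assert fit.theta2 == pytest.approx(-2.0, rel=1e-9)


class TestEmg:
    def _small_schedule(self, rng, n=12):
        sched = rs.generate_schedule(
            rs.ProtocolConfig(n_blocks=1, trials_per_condition_per_block=n // 3),
            rng)
        return sched

    def test_detector_recovers_injected_onsets(self, rng):
        sched = self._small_schedule(rng)
        rts = rng.normal(150, 20, len(sched))
        sig, onset_samples = rs.synthesize_emg(sched, rts, EmgConfig(), rng)
        out, _ = rs.batch_onsets({"1DI": sig}, sched)
        err = out["rt_1DI_ms"].to_numpy() - rts
        assert np.all(np.abs(err) <= 2.0)

    def test_zero_amplitude_no_onsets(self, rng):
        sched = self._small_schedule(rng)
        rts = np.full(len(sched), 150.0)
        sig, _ = rs.synthesize_emg(sched, rts, EmgConfig(burst_amplitude=0.0), rng)
        out, _ = rs.batch_onsets({"1DI": sig}, sched)
        assert out["rt_1DI_ms"].isna().all()

    def test_seeded_traces_bit_identical(self, rng):
        sched = self._small_schedule(rng)
        rts = np.full(len(sched), 150.0)
        a, _ = rs.synthesize_emg(sched, rts, EmgConfig(), np.random.default_rng(9))
        b, _ = rs.synthesize_emg(sched, rts, EmgConfig(), np.random.default_rng(9))
        assert np.array_equal(a.values, b.values)

    def test_ground_truth_onset_sample_rule(self, rng):
        sched = self._small_schedule(rng)
        rts = rng.normal(150, 20, len(sched))
        sig, onset_samples = rs.synthesize_emg(sched, rts, EmgConfig(), rng)
        cues = sched["cue_time_s"].to_numpy()
        expected = np.rint((cues + rts / 1000.0 - sig.t0_s) * sig.rate_hz)
        assert np.array_equal(onset_samples, expected.astype(int))

    def test_overlapping_bursts_rejected(self, rng):
        sched = pd.DataFrame({"cue_time_s": [10.0, 10.05]})
        with pytest.raises(ValueError, match="overlap"):
            rs.synthesize_emg(sched, np.array([100.0, 100.0]), EmgConfig(), rng)


class TestDataset:
    def test_seed_reproducibility_and_structure(self):
        cfg = rs.DatasetConfig(
            n_participants=2,
            protocol=rs.ProtocolConfig(n_blocks=1, trials_per_condition_per_block=4),
            breathing=rs.BreathingConfig(duration_s=250.0),
            seed=42)
        a = rs.generate_dataset(cfg)
        b = rs.generate_dataset(cfg)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        assert len(a.participants) == 2
        assert len(a.trials) == 2 * 12
        # substreams independent: different participants differ
        t = a.trials
        assert not np.array_equal(
            t[t["participant"] == "P01"]["rt_1DI_ms"].to_numpy(),
            t[t["participant"] == "P02"]["rt_1DI_ms"].to_numpy())

    def test_every_cue_has_ground_truth_phase(self):
        cfg = rs.DatasetConfig(
            n_participants=1,
            protocol=rs.ProtocolConfig(n_blocks=1, trials_per_condition_per_block=5),
            seed=7)
        ds = rs.generate_dataset(cfg)
        assert ds.trials["phase"].notna().all()
        assert ds.trials["phase"].between(1, 6).all()

    def test_breathing_span_covers_schedule(self):
        cfg = rs.ProtocolConfig()
        assert _required_breathing_duration(cfg) > cfg.n_trials * cfg.iti_max_s
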