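"""Generator: schedules, reel kinematics, latent trajectories, choices and
EEG epochs."""

import numpy as np
import pytest

from dynexpect import synthdata
from dynexpect.outcomes import CONDITION_ORDER, OutcomeClass
from dynexpect.synthdata import (
    DECEL_RANGE,
    PENULTIMATE_ENTRY,
    SPIN_RANGE,
    STUDY_DESIGNS,
    SimulationConfig,
    build_trial_schedule,
    certainty_signal,
    latent_expectation,
    sample_trial_timing,
    simulate_behavioral_cohort,
    simulate_choices,
    simulate_epochs,
)


class TestSchedules:
    def test_study1_design_counts(self):
        sched = build_trial_schedule(STUDY_DESIGNS[1], blocks=3, seed=0)
        counts = sched.counts()
        assert len(sched.trials) == 150
        assert counts[OutcomeClass.FULL_AWAY] == 75
        assert counts[OutcomeClass.MATCH] == 25

    def test_study2_design_counts(self):
        sched = build_trial_schedule(STUDY_DESIGNS[2], blocks=1, seed=0)
        assert len(sched.trials) == 36
        assert sched.counts()[OutcomeClass.FULL_AWAY] == 18

    def test_zero_design_is_empty(self):
        sched = build_trial_schedule({oc: 0 for oc in CONDITION_ORDER}, blocks=1, seed=0)
        assert sched.trials == []

    def test_indivisible_blocks_raise(self):
        with pytest.raises(ValueError, match="divide"):
            build_trial_schedule(STUDY_DESIGNS[1], blocks=4, seed=0)

    def test_order_is_a_seeded_shuffle(self):
        s1 = build_trial_schedule(STUDY_DESIGNS[2], blocks=1, seed=5)
        s2 = build_trial_schedule(STUDY_DESIGNS[2], blocks=1, seed=5)
        s3 = build_trial_schedule(STUDY_DESIGNS[2], blocks=1, seed=6)
        order1 = [oc for _, oc, _, _ in s1.trials]
        assert order1 == [oc for _, oc, _, _ in s2.trials]
        assert order1 != [oc for _, oc, _, _ in s3.trials]


class TestTiming:
    def test_durations_inside_printed_ranges(self, rng):
        for _ in range(2000):
            t = sample_trial_timing(OutcomeClass.FULL_AWAY, rng)
            assert SPIN_RANGE[0] <= t.spin_duration <= SPIN_RANGE[1]
            assert DECEL_RANGE[0] <= t.decel_duration <= DECEL_RANGE[1]
            assert t.penultimate_entry < 0

    def test_mean_penultimate_entry_matches_calibration(self, rng):
        entries = [
            sample_trial_timing(OutcomeClass.MATCH, rng).penultimate_entry
            for _ in range(10_000)
        ]
        assert np.mean(entries) == pytest.approx(PENULTIMATE_ENTRY, abs=0.05)

    def test_item_passages_strictly_increasing(self, rng):
        t = sample_trial_timing(OutcomeClass.NEAR_BEFORE, rng)
        times = [tp for _, tp in t.item_passages]
        assert all(a < b for a, b in zip(times, times[1:]))
        assert times[-1] == pytest.approx(t.penultimate_entry)

    def test_determinism_under_seed(self):
        t1 = sample_trial_timing(OutcomeClass.NEAR_AFTER, np.random.default_rng(9))
        t2 = sample_trial_timing(OutcomeClass.NEAR_AFTER, np.random.default_rng(9))
        assert t1 == t2


class TestLatentTrajectories:
    @pytest.fixture
    def timing(self, rng):
        return sample_trial_timing(OutcomeClass.NEAR_AFTER, rng)

    def test_full_away_low_at_stop(self, timing, grid_3s):
        traj = latent_expectation(OutcomeClass.FULL_AWAY, timing, grid_3s)
        assert traj.expectation[-1] <= 0.1

    def test_near_after_peaks_at_penultimate_entry(self, timing, grid_3s):
        traj = latent_expectation(OutcomeClass.NEAR_AFTER, timing, grid_3s)
        t_peak = grid_3s[np.argmax(traj.expectation)]
        assert t_peak <= timing.penultimate_entry + 0.05
        assert traj.expectation[-1] < traj.expectation.max()

    def test_match_rises_over_final_second(self, timing, grid_3s):
        traj = latent_expectation(OutcomeClass.MATCH, timing, grid_3s)
        p = traj.expectation
        assert p[-1] - np.interp(-1.0, grid_3s, p) > 0
        late = p[grid_3s >= -0.5]
        assert np.all(np.diff(late) >= -1e-12)

    def test_all_expectations_in_unit_interval(self, rng, grid_3s):
        for oc in CONDITION_ORDER:
            t = sample_trial_timing(oc, rng)
            traj = latent_expectation(oc, t, grid_3s)
            assert np.all((traj.expectation >= 0) & (traj.expectation <= 1))

    def test_grid_outside_epoch_raises(self, timing):
        with pytest.raises(ValueError):
            latent_expectation(OutcomeClass.MATCH, timing, np.array([-3.5, -1.0]))


class TestChoices:
    def _traj_and_timing(self, oc, seed=0):
        rng = np.random.default_rng(seed)
        timing = sample_trial_timing(oc, rng)
        grid = np.arange(-3.0, 1e-9, 0.05)
        return latent_expectation(oc, timing, grid), timing

    def test_zero_hazard_never_switches(self):
        traj, timing = self._traj_and_timing(OutcomeClass.MATCH)
        cfg = SimulationConfig(switch_hazard=0.0)
        _, v = simulate_choices(traj, 10, timing, cfg, np.random.default_rng(0))
        assert len(set(v.tolist())) == 1

    def test_dominant_option_wins_with_high_hazard(self):
        traj, timing = self._traj_and_timing(OutcomeClass.MATCH)
        traj.expectation[:] = 1.0
        cfg = SimulationConfig(switch_hazard=500.0, choice_lag=0.0)
        _, v = simulate_choices(traj, 1, timing, cfg, np.random.default_rng(3))
        assert v[-1] == 1

    def test_values_binary_and_grid_50ms(self):
        traj, timing = self._traj_and_timing(OutcomeClass.FULL_AWAY)
        g, v = simulate_choices(traj, 15, timing, SimulationConfig(), np.random.default_rng(1))
        assert set(np.unique(v)) <= {0, 1}
        assert np.allclose(np.diff(g), 0.05)
        assert g[-1] == pytest.approx(0.75)

    def test_invalid_sure_amount_raises(self):
        traj, timing = self._traj_and_timing(OutcomeClass.MATCH)
        with pytest.raises(ValueError):
            simulate_choices(traj, 13, timing, SimulationConfig(), np.random.default_rng(0))

    def test_group_means_reproduce_class_ordering(self):
        # Monte-Carlo on the generator: at t = -0.25 s the mean bet state
        # orders MATCH > NEAR_BEFORE > NEAR_AFTER > FULL_AWAY
        cfg = SimulationConfig(seed=11)
        rng = np.random.default_rng(11)
        means = []
        for oc in CONDITION_ORDER:
            acc = []
            for _ in range(200):
                timing = sample_trial_timing(oc, rng)
                traj = latent_expectation(oc, timing, np.arange(-3.0, 1e-9, 0.05))
                sure = float(rng.choice(synthdata.SURE_AMOUNTS))
                g, v = simulate_choices(traj, sure, timing, cfg, rng)
                acc.append(np.interp(-0.25, g, v))
            means.append(np.mean(acc))
        assert means[0] > means[1] > means[2] > means[3]


class TestEpochs:
    def _small_cfg(self, **kw):
        design = {
            OutcomeClass.MATCH: 2,
            OutcomeClass.NEAR_BEFORE: 2,
            OutcomeClass.NEAR_AFTER: 2,
            OutcomeClass.FULL_AWAY: 2,
        }
        return SimulationConfig(design=design, blocks=1, sampling_rate_eeg=128.0, **kw)

    def test_noise_free_cz_equals_negated_certainty(self):
        cfg = self._small_cfg(eeg_noise_sd=0.0)
        sched = build_trial_schedule(cfg.design, 1, seed=0)
        es = simulate_epochs(sched, cfg, np.random.default_rng(0))
        ep = next(e for e in es.epochs if e.outcome is OutcomeClass.FULL_AWAY)
        cz = es.channel_index("Cz")
        mask = (ep.times >= -3.0) & (ep.times <= 0.0)
        timing = next(t for _, oc, _, t in sched.trials if oc is OutcomeClass.FULL_AWAY)
        traj = latent_expectation(OutcomeClass.FULL_AWAY, timing, ep.times[mask])
        expected = -cfg.eeg_ramp_gain * certainty_signal(traj)
        assert np.allclose(ep.data[cz, mask], expected, atol=1e-12)

    def test_noise_free_match_more_negative_than_full_away(self):
        cfg = self._small_cfg(eeg_noise_sd=0.0)
        sched = build_trial_schedule(cfg.design, 1, seed=1)
        es = simulate_epochs(sched, cfg, np.random.default_rng(1))
        cz = es.channel_index("Cz")
        t_idx = np.argmin(np.abs(es.epochs[0].times - (-0.25)))
        match = [e.data[cz, t_idx] for e in es.epochs if e.outcome is OutcomeClass.MATCH]
        fa = [e.data[cz, t_idx] for e in es.epochs if e.outcome is OutcomeClass.FULL_AWAY]
        assert np.mean(match) < np.mean(fa)

    def test_same_seed_bit_identical(self):
        cfg = self._small_cfg()
        sched = build_trial_schedule(cfg.design, 1, seed=2)
        es1 = simulate_epochs(sched, cfg, np.random.default_rng(7))
        es2 = simulate_epochs(sched, cfg, np.random.default_rng(7))
        for a, b in zip(es1.epochs, es2.epochs):
            assert np.array_equal(a.data, b.data)

    def test_epoch_covers_required_span_and_baseline(self):
        cfg = self._small_cfg()
        sched = build_trial_schedule(cfg.design, 1, seed=3)
        es = simulate_epochs(sched, cfg, np.random.default_rng(0))
        for ep in es.epochs:
            assert ep.times[0] <= ep.spin_onset - 0.2
            assert ep.times[0] <= -3.0 and ep.times[-1] >= 1.0


class TestCohortDeterminism:
    def test_behavioral_cohort_identical_under_seed(self):
        cfg = SimulationConfig.for_study(2, n_subjects=3, seed=42)
        log1 = simulate_behavioral_cohort(cfg)
        log2 = simulate_behavioral_cohort(cfg)
        assert log1.equals(log2)

    def test_design_conservation_per_participant(self):
        cfg = SimulationConfig.for_study(2, n_subjects=2, seed=1)
        log = simulate_behavioral_cohort(cfg)
        for _, g in log.groupby("participant"):
            per_trial = g.groupby("trial")["outcome"].first()
            counts = per_trial.value_counts()
            assert counts["full_away"] == 18
            assert counts["match"] == 6
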