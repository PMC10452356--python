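"""Surrogate-subject generation, averaging and motion CSV I/O."""

import numpy as np
import pytest

from armclone import (
    MotionDataset,
    SubjectProfile,
    average_subjects,
    forward_kinematics,
    minimum_jerk_profile,
    read_dataset,
    synthesize_subject,
    synthesize_trial,
    write_dataset,
)
from armclone.subjects import SchemaError, recorded_to_full


class TestMinimumJerk:
    def test_boundary_conditions(self):
        assert minimum_jerk_profile(0.0) == 0.0
        assert minimum_jerk_profile(1.0) == 1.0
        assert minimum_jerk_profile(0.5) == pytest.approx(0.5)
        # zero end velocities: finite-difference slope vanishes at the ends
        h = 1e-6
        assert minimum_jerk_profile(h) / h < 1e-4
        assert (1 - minimum_jerk_profile(1 - h)) / h < 1e-4

    def test_peak_speed_is_15_over_8(self):
        tau = np.linspace(0, 1, 100_001)
        speed = np.gradient(minimum_jerk_profile(tau), tau)
        assert speed.max() == pytest.approx(1.875, abs=1e-6)
        assert tau[speed.argmax()] == pytest.approx(0.5, abs=1e-3)

    def test_range_error(self):
        with pytest.raises(ValueError):
            minimum_jerk_profile(1.2)


class TestSynthesizeTrial:
    def test_noiseless_trial_follows_minimum_jerk_path(
        self, noiseless_profile, arm, grid, timing
    ):
        tr = synthesize_trial(noiseless_profile, arm, grid, timing, 3, 1, 1)
        tips = forward_kinematics(arm, recorded_to_full(tr.angles)).fingertip
        target = grid.target(3)
        n_reach, n_touch, n_return, n_wait = tr.phase_samples
        s = minimum_jerk_profile(np.arange(n_reach) / n_reach)
        ideal_reach = grid.center + s[:, None] * (target - grid.center)
        dev = np.linalg.norm(tips[:n_reach] - ideal_reach, axis=1)
        assert dev.max() < 1e-4
        np.testing.assert_allclose(tips[n_reach], target, atol=1e-4)
        np.testing.assert_allclose(tips[-1], grid.center, atol=1e-4)

    def test_bit_identical_on_repeat(self, arm, grid, timing):
        p = SubjectProfile("A", 30.0, seed=9)
        a = synthesize_trial(p, arm, grid, timing, 5, 2, 1)
        b = synthesize_trial(p, arm, grid, timing, 5, 2, 1)
        assert np.array_equal(a.angles, b.angles)
        assert np.array_equal(a.times, b.times)

    def test_noise_sd_matches_process(self, arm, grid, timing):
        """Empirical deviation sd stays near the configured 2 degrees."""
        noisy = SubjectProfile("N", 24.0, 2.0, 0.3, 0.0, seed=11)
        clean = SubjectProfile("N", 24.0, 0.0, 0.3, 0.0, seed=11)
        devs = []
        for tid in range(1, 9):
            for rep in range(1, 5):
                a = synthesize_trial(noisy, arm, grid, timing, tid, rep, 1)
                b = synthesize_trial(clean, arm, grid, timing, tid, rep, 1)
                devs.append(a.angles - b.angles)
        sd = np.concatenate(devs).std(axis=0)
        assert np.all(sd > 1.5) and np.all(sd < 2.5)

    def test_trials_satisfy_invariants(self, noisy_dataset, arm):
        noisy_dataset.validate(arm=arm)


class TestSynthesizeSubject:
    def test_trial_counts(self, arm, grid, timing):
        p = SubjectProfile("A", 30.0, seed=3)
        assert len(synthesize_subject(p, arm, grid, timing, 4, 2)) == 64
        assert len(synthesize_subject(p, arm, grid, timing, 1, 1)) == 8

    def test_distinct_seeds_give_distinct_datasets(self, arm, grid, timing):
        sets = [
            synthesize_subject(
                SubjectProfile(f"S{k}", 24.0, seed=50 + k), arm, grid, timing, 1, 1
            )
            for k in range(3)
        ]
        for i in range(3):
            for j in range(i + 1, 3):
                assert not np.array_equal(
                    sets[i].trials[0].angles, sets[j].trials[0].angles
                )

    def test_equal_swivel_noiseless_subjects_share_synergy(self, arm, grid, timing):
        """Same swivel + no noise -> identical trials despite different seeds."""
        a = SubjectProfile("A", 24.0, 0.0, 0.3, 0.0, seed=1)
        b = SubjectProfile("B", 24.0, 0.0, 0.3, 0.0, seed=2)
        ta = synthesize_trial(a, arm, grid, timing, 4, 1, 1)
        tb = synthesize_trial(b, arm, grid, timing, 4, 1, 1)
        np.testing.assert_allclose(ta.angles, tb.angles, atol=1e-12)


class TestAveraging:
    def test_identity_and_linearity(self, noiseless_dataset, grid, timing):
        from dataclasses import replace

        one = average_subjects([noiseless_dataset])
        two_trials = [
            replace(tr, subject_id="S9", angles=tr.angles + 2.0)
            for tr in noiseless_dataset.trials
        ]
        shifted = MotionDataset(two_trials, grid=grid, timing=timing)
        avg = average_subjects([noiseless_dataset, shifted])
        for tr_avg, tr_one in zip(avg.trials, one.trials):
            np.testing.assert_allclose(tr_avg.angles, tr_one.angles + 1.0, atol=1e-9)
        assert avg.trials[0].subject_id == "AVG"

    def test_average_within_pointwise_hull(self, arm, grid, timing):
        sets = [
            synthesize_subject(
                SubjectProfile(f"S{k}", 18.0 + 6 * k, seed=60 + k),
                arm,
                grid,
                timing,
                1,
                1,
            )
            for k in range(3)
        ]
        avg = average_subjects(sets)
        from armclone.subjects import _resample_trial

        for i, tr in enumerate(avg.trials):
            stack = np.stack(
                [_resample_trial(s.trials[i], timing).angles for s in sets]
            )
            assert np.all(tr.angles >= stack.min(axis=0) - 1e-9)
            assert np.all(tr.angles <= stack.max(axis=0) + 1e-9)

    def test_mismatched_structure_rejected(self, noiseless_dataset, arm, grid, timing):
        other = synthesize_subject(
            SubjectProfile("B", 30.0, seed=2), arm, grid, timing, 2, 1
        )
        with pytest.raises(ValueError, match="mismatch"):
            average_subjects([noiseless_dataset, other])


class TestCsvRoundtrip:
    def test_lossless_roundtrip(self, noisy_dataset, tmp_path):
        path = tmp_path / "subject.csv"
        write_dataset(noisy_dataset, path)
        back = read_dataset(path)
        assert len(back) == len(noisy_dataset)
        orig = {tr.key: tr for tr in noisy_dataset.trials}
        for tr in back.trials:
            np.testing.assert_allclose(tr.angles, orig[tr.key].angles, atol=1e-9)
            np.testing.assert_allclose(tr.times, orig[tr.key].times, atol=1e-9)

    def test_row_count_matches_structure(self, noiseless_dataset, tmp_path):
        path = tmp_path / "d.csv"
        write_dataset(noiseless_dataset, path)
        n_lines = sum(1 for _ in open(path)) - 1  # header
        assert n_lines == sum(tr.n_samples for tr in noiseless_dataset.trials)
        # noiseless/jitterless trials all have the nominal 275 samples
        assert {tr.n_samples for tr in noiseless_dataset.trials} == {275}

    def test_missing_column_raises(self, noisy_dataset, tmp_path):
        import pandas as pd

        path = tmp_path / "bad.csv"
        write_dataset(noisy_dataset, path)
        frame = pd.read_csv(path).drop(columns=["E_flex"])
        frame.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="E_flex"):
            read_dataset(path)

    def test_duplicate_trial_keys_rejected(self, noiseless_dataset):
        with pytest.raises(SchemaError, match="duplicate"):
            MotionDataset(
                noiseless_dataset.trials + [noiseless_dataset.trials[0]]
            )
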