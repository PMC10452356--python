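"""Correlation, RMSE and target-reaching-error metrics."""

import numpy as np
import pytest

from armclone import (
    correlation_matrix,
    interpret_r,
    pearson_r,
    reaching_error_cm,
    rmse_deg,
    synthesize_trial,
)
from armclone.evaluation import UndefinedCorrelationError
from armclone.subjects import SubjectProfile


class TestPearson:
    def test_perfect_positive_and_negative(self):
        a = np.array([1.0, 2.0, 5.0, 7.0])
        assert pearson_r(a, 2 * a + 1) == pytest.approx(1.0)
        assert pearson_r(a, -a) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_affine_invariance(self, rng):
        a = rng.standard_normal(50)
        b = rng.standard_normal(50)
        r = pearson_r(a, b)
        assert pearson_r(3 * a + 2, b) == pytest.approx(r, abs=1e-12)
        assert pearson_r(a, 0.5 * b - 7) == pytest.approx(r, abs=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestInterpretR:
    @pytest.mark.parametrize(
        "r,label",
        [
            (0.85, "strong positive"),
            (0.7, "strong positive"),  # boundary goes to the stronger band
            (0.5, "distinct positive"),
            (0.3, "distinct positive"),
            (0.2, "weak positive"),
            (0.1, "weak positive"),
            (0.0, "not linear"),
            (-0.05, "not linear"),
            (-0.1, "weak negative"),
            (-0.5, "distinct negative"),
            (-0.7, "strong negative"),
            (-1.0, "strong negative"),
            (1.0, "strong positive"),
        ],
    )
    def test_band_assignment(self, r, label):
        assert interpret_r(r) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            interpret_r(1.5)


class TestRmse:
    def test_trivial_cases(self):
        a = np.array([1.0, 2.0, 3.0])
        assert rmse_deg(a, a) == 0.0
        assert rmse_deg(a + 2.0, a) == pytest.approx(2.0)

    def test_hand_arithmetic(self):
        assert rmse_deg([0.0, 3.0, 4.0], [0.0, 0.0, 0.0]) == pytest.approx(
            np.sqrt(25.0 / 3.0)
        )

    def test_matches_bruteforce_loop(self, rng):
        p = rng.standard_normal(200)
        a = rng.standard_normal(200)
        acc = 0.0
        for x, y in zip(p, a):
            acc += (x - y) ** 2
        assert rmse_deg(p, a) == pytest.approx(np.sqrt(acc / 200), abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            rmse_deg([1.0, 2.0], [1.0])


class TestCorrelationMatrix:
    def test_self_comparison_is_unity(self, noisy_dataset, timing):
        mat = correlation_matrix([noisy_dataset], noisy_dataset, 3, timing)
        assert mat.shape == (1, 5)
        np.testing.assert_allclose(mat.to_numpy(), 1.0, atol=1e-12)

    def test_sign_flip_negates_channel(self, noisy_dataset, grid, timing):
        from dataclasses import replace
        from armclone import MotionDataset

        flipped_trials = [
            replace(
                tr,
                subject_id="F",
                angles=tr.angles * np.array([1, 1, 1, 1, -1.0]),
            )
            for tr in noisy_dataset.trials
        ]
        flipped = MotionDataset(flipped_trials, grid=grid, timing=timing)
        base = correlation_matrix([noisy_dataset], noisy_dataset, 5, timing)
        mat = correlation_matrix([flipped], noisy_dataset, 5, timing)
        assert mat.iloc[0]["E_flex"] == pytest.approx(-base.iloc[0]["E_flex"])

    def test_missing_target_raises(self, noisy_dataset, timing):
        with pytest.raises(ValueError, match="no trials"):
            correlation_matrix([noisy_dataset], noisy_dataset, 99, timing)


class TestReachingError:
    @pytest.fixture(scope="class")
    def trial(self, arm, grid, timing):
        p = SubjectProfile("R", 24.0, 0.0, 0.3, 0.0, seed=4)
        return synthesize_trial(p, arm, grid, timing, 1, 1, 1)

    def test_exact_elbow_gives_zero(self, trial, arm, grid):
        assert reaching_error_cm(trial, trial, arm, grid) == 0.0

    def test_constructed_offset_recovered(self, trial, arm, grid):
        """An elbow-flexion offset solved to shift the apex fingertip by
        exactly 3 cm must yield a 3.0 cm reaching error."""
        from dataclasses import replace
        from scipy.optimize import brentq

        from armclone import forward_kinematics
        from armclone.subjects import recorded_to_full

        tips = forward_kinematics(arm, recorded_to_full(trial.angles)).fingertip
        apex = int(np.argmax(np.linalg.norm(tips - grid.center, axis=-1)))

        def apex_shift(delta):
            angles = trial.angles.copy()
            angles[:, 4] += delta
            t2 = forward_kinematics(arm, recorded_to_full(angles)).fingertip
            return float(np.linalg.norm(t2[apex] - tips[apex])) - 0.03

        delta = brentq(apex_shift, 0.0, 30.0, xtol=1e-12)
        pred = replace(trial, angles=trial.angles + np.array([0, 0, 0, 0, delta]))
        assert reaching_error_cm(pred, trial, arm, grid) == pytest.approx(
            3.0, abs=1e-6
        )

    def test_only_apex_sample_matters(self, trial, arm, grid):
        from dataclasses import replace

        tips_apex = None
        angles = trial.angles.copy()
        # corrupt elbow channels everywhere except a window around the apex
        from armclone import forward_kinematics
        from armclone.subjects import recorded_to_full

        tips = forward_kinematics(arm, recorded_to_full(trial.angles)).fingertip
        apex = int(np.argmax(np.linalg.norm(tips - grid.center, axis=-1)))
        mask = np.ones(len(angles), bool)
        mask[apex] = False
        angles[mask, 3:] += 25.0
        pred = replace(trial, angles=angles)
        assert reaching_error_cm(pred, trial, arm, grid) == pytest.approx(0.0)

    def test_mismatched_targets_rejected(self, trial, arm, grid, timing):
        p = SubjectProfile("R", 24.0, 0.0, 0.3, 0.0, seed=4)
        other = synthesize_trial(p, arm, grid, timing, 2, 1, 1)
        with pytest.raises(ValueError, match="target"):
            reaching_error_cm(other, trial, arm, grid)
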