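"""Evaluation metrics: Pearson correlation, RMSE and target-reaching error.

Pearson's r quantifies how well a predicted elbow-angle trace follows
the shape of the measured one; RMSE (degrees) its average magnitude
error; and the target-reaching error (cm) the task-space consequence of
elbow mispredictions, obtained by replaying measured shoulder angles
with predicted vs measured elbow angles through the forward kinematics
and comparing fingertip positions at the apex of the reach.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import ArmModel, forward_kinematics
from .subjects import (
    ANGLE_COLUMNS,
    MotionDataset,
    MotionTrial,
    _resample_trial,
    recorded_to_full,
)
from .task import PhaseTiming, TargetGrid

__all__ = [
    "UndefinedCorrelationError",
    "pearson_r",
    "interpret_r",
    "rmse_deg",
    "correlation_matrix",
    "reaching_error_cm",
    "MetricsReport",
    "compute_metrics",
]


class UndefinedCorrelationError(ValueError):
    """Raised for correlation of a constant series (zero variance)."""


def pearson_r(a, b) -> float:
    """Product-moment correlation of two equal-length series."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if len(a) < 2:
        raise ValueError("need at least two samples")
    if np.std(a) < 1e-12 or np.std(b) < 1e-12:
        raise UndefinedCorrelationError("correlation undefined for constant series")
    return float(np.corrcoef(a, b)[0, 1])


#: Interpretation bands for |r|; boundaries belong to the stronger band.
_BANDS = (
    (0.7, "strong"),
    (0.3, "distinct"),
    (0.1, "weak"),
)


def interpret_r(r: float) -> str:
    """Qualitative relationship label for a correlation coefficient."""
    if not -1.0 <= r <= 1.0 + 1e-12:
        raise ValueError(f"|r| must be <= 1, got {r}")
    mag = abs(r)
    for lo, name in _BANDS:
        if mag >= lo:
            sign = "positive" if r > 0 else "negative"
            return f"{name} {sign}"
    return "not linear"


def rmse_deg(pred, actual) -> float:
    """Root-mean-squared error sqrt(mean((pred - actual)^2)), degrees."""
    pred = np.asarray(pred, float)
    actual = np.asarray(actual, float)
    if pred.shape != actual.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {actual.shape}")
    if pred.size == 0:
        raise ValueError("empty series")
    return float(np.sqrt(np.mean((pred - actual) ** 2)))


def _mean_trial_angles(
    dataset: MotionDataset, target_id: int, timing: PhaseTiming
) -> np.ndarray:
    """Time-normalized mean trial (n, 5) over a dataset's trials to a target."""
    trs = [tr for tr in dataset.trials if tr.target_id == target_id]
    if not trs:
        raise ValueError(f"dataset has no trials for target {target_id}")
    res = [_resample_trial(tr, timing) for tr in trs]
    return np.mean([r.angles for r in res], axis=0)


def correlation_matrix(
    datasets: list[MotionDataset],
    reference: MotionDataset,
    target_id: int,
    timing: PhaseTiming,
) -> pd.DataFrame:
    """Pearson r of each dataset's mean trial against the reference's.

    Rows = datasets (labelled by their subject ids / provenance),
    columns = the five recorded channels.
    """
    ref = _mean_trial_angles(reference, target_id, timing)
    rows = {}
    for ds in datasets:
        label = "+".join(ds.subject_ids) if ds.subject_ids else ds.provenance
        mean = _mean_trial_angles(ds, target_id, timing)
        rows[label] = [pearson_r(mean[:, c], ref[:, c]) for c in range(5)]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(ANGLE_COLUMNS)
    )


def reaching_error_cm(
    pred_motion: MotionTrial,
    actual_motion: MotionTrial,
    arm: ArmModel,
    grid: TargetGrid,
) -> float:
    """Fingertip discrepancy (cm) at the apex of the actual reach.

    Both trials are replayed through the forward kinematics with the
    wrist neutral: the actual trial as recorded, the predicted trial
    with its (predicted) elbow angles but the actual shoulder angles.
    The apex is the actual trial's sample of maximum fingertip distance
    from the grid center.
    """
    if pred_motion.target_id != actual_motion.target_id:
        raise ValueError("trials must share target_id")
    if pred_motion.n_samples != actual_motion.n_samples:
        raise ValueError("trials must share timing (sample count)")
    pred_angles = pred_motion.angles.copy()
    pred_angles[:, :3] = actual_motion.angles[:, :3]  # shoulder is shared
    tips_actual = forward_kinematics(arm, recorded_to_full(actual_motion.angles)).fingertip
    tips_pred = forward_kinematics(arm, recorded_to_full(pred_angles)).fingertip
    dist = np.linalg.norm(tips_actual - grid.center, axis=-1)
    apex = int(np.argmax(dist))
    ps = actual_motion.phase_samples
    if ps is not None and apex >= ps[0] + ps[1]:
        # Angle noise can push the farthest sample slightly past the touch
        # phase; the apex is used regardless (identical message so the
        # warning is reported once, not once per trial).
        warnings.warn("reach apex outside reach/touch phases; using it anyway")
    return float(np.linalg.norm(tips_pred[apex] - tips_actual[apex]) * 100.0)


@dataclass
class MetricsReport:
    """Per-trial and aggregated metrics of one model on one test set.

    ``pearson``: r per (subject, target, elbow channel), concatenated
    over repetitions/sessions.  ``rmse``: per-subject RMSE per channel
    and overall (all samples and both elbow channels concatenated).
    ``reaching``: per-trial apex fingertip error in cm.
    """

    pearson: pd.DataFrame
    rmse: pd.DataFrame
    reaching: pd.DataFrame

    @property
    def overall_rmse_deg(self) -> float:
        sel = self.rmse[self.rmse.channel == "overall"]
        return float(sel.rmse_deg.mean())

    @property
    def mean_reaching_error_cm(self) -> float:
        return float(self.reaching.error_cm.mean())

    def to_json_dict(self) -> dict:
        return {
            "pearson": self.pearson.to_dict(orient="records"),
            "rmse": self.rmse.to_dict(orient="records"),
            "reaching": self.reaching.to_dict(orient="records"),
            "overall_rmse_deg": self.overall_rmse_deg,
            "mean_reaching_error_cm": self.mean_reaching_error_cm,
        }


def compute_metrics(
    pred: MotionDataset,
    actual: MotionDataset,
    arm: ArmModel,
    grid: TargetGrid,
) -> MetricsReport:
    """Compare predicted elbow angles against the measured test set.

    Trials are matched by (subject, target, repetition, session); the
    predicted dataset must cover every actual trial.
    """
    pred_by_key = {tr.key: tr for tr in pred.trials}
    pearson_rows, reaching_rows = [], []
    per_subject: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    by_subj_target: dict[tuple, list[tuple[np.ndarray, np.ndarray]]] = {}
    for tr in actual.trials:
        if tr.key not in pred_by_key:
            raise ValueError(f"missing prediction for trial {tr.key}")
        pr = pred_by_key[tr.key]
        per_subject.setdefault(tr.subject_id, []).append(
            (pr.angles[:, 3:5], tr.angles[:, 3:5])
        )
        by_subj_target.setdefault((tr.subject_id, tr.target_id), []).append(
            (pr.angles[:, 3:5], tr.angles[:, 3:5])
        )
        reaching_rows.append(
            {
                "subject_id": tr.subject_id,
                "target_id": tr.target_id,
                "repetition": tr.repetition,
                "session": tr.session,
                "error_cm": reaching_error_cm(pr, tr, arm, grid),
            }
        )
    for (sid, tid), pairs in sorted(by_subj_target.items()):
        p = np.concatenate([a for a, _ in pairs])
        a = np.concatenate([b for _, b in pairs])
        for ci, ch in enumerate(("E_pron", "E_flex")):
            pearson_rows.append(
                {
                    "subject_id": sid,
                    "target_id": tid,
                    "channel": ch,
                    "r": pearson_r(p[:, ci], a[:, ci]),
                }
            )
    rmse_rows = []
    for sid, pairs in sorted(per_subject.items()):
        p = np.concatenate([a for a, _ in pairs])
        a = np.concatenate([b for _, b in pairs])
        for ci, ch in enumerate(("E_pron", "E_flex")):
            rmse_rows.append(
                {"subject_id": sid, "channel": ch, "rmse_deg": rmse_deg(p[:, ci], a[:, ci])}
            )
        rmse_rows.append(
            {
                "subject_id": sid,
                "channel": "overall",
                "rmse_deg": rmse_deg(p.ravel(), a.ravel()),
            }
        )
    return MetricsReport(
        pearson=pd.DataFrame(pearson_rows),
        rmse=pd.DataFrame(rmse_rows),
        reaching=pd.DataFrame(reaching_rows),
    )
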