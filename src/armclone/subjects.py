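"""Surrogate human subjects and the motion-dataset containers.

A surrogate subject performs the center-out-center task with a straight
fingertip path, minimum-jerk time scaling, a subject-specific elbow
swivel angle (their redundancy-resolution "style"), smooth
Ornstein-Uhlenbeck angle noise and mild per-phase timing jitter.  With
equal swivel and zero noise every subject produces identical trials, so
the shoulder-to-elbow synergy a decoder must learn is exactly shared;
the default profiles spread swivel across a plausible human range to
make cross-subject transfer nontrivial but learnable.

The recorded channels are the five angles (S_rot, S_flex, S_abd,
E_pron, E_flex) in degrees; the two wrist angles are internal to the
arm model and held neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import (
    ArmModel,
    RECORDED_JOINTS,
    forward_kinematics,
    inverse_kinematics_swivel,
)
from .task import PhaseTiming, TargetGrid

__all__ = [
    "ANGLE_COLUMNS",
    "CSV_COLUMNS",
    "SchemaError",
    "SubjectProfile",
    "MotionTrial",
    "MotionDataset",
    "default_profiles",
    "minimum_jerk_profile",
    "synthesize_trial",
    "synthesize_subject",
    "average_subjects",
    "read_dataset",
    "write_dataset",
    "recorded_to_full",
]

ANGLE_COLUMNS = ("S_rot", "S_flex", "S_abd", "E_pron", "E_flex")
CSV_COLUMNS = ("subject_id", "target_id", "repetition", "session", "t") + ANGLE_COLUMNS


class SchemaError(ValueError):
    """Raised when a motion CSV or dataset violates the schema."""


class IncompatibleDatasetsError(ValueError):
    """Raised when datasets with mismatched structure are combined."""


def recorded_to_full(angles: np.ndarray) -> np.ndarray:
    """Expand (..., 5) recorded angles to (..., 7) joint vectors, wrist neutral."""
    angles = np.asarray(angles, float)
    q = np.zeros(angles.shape[:-1] + (7,))
    for out_col, joint_idx in enumerate(RECORDED_JOINTS):
        q[..., joint_idx] = angles[..., out_col]
    return q


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters of one surrogate subject."""

    subject_id: str
    swivel_deg: float
    angle_noise_sd: float = 2.0
    noise_corr_time_s: float = 0.3
    timing_jitter_frac: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.angle_noise_sd < 0:
            raise ValueError("angle_noise_sd must be >= 0")
        if not 0 <= self.timing_jitter_frac < 0.5:
            raise ValueError("timing_jitter_frac must be in [0, 0.5)")


def default_profiles() -> list[SubjectProfile]:
    """The six default surrogate subjects: swivel 12..42 deg in 6-deg steps."""
    return [
        SubjectProfile(
            subject_id=f"S{k + 1}",
            swivel_deg=12.0 + 6.0 * k,
            angle_noise_sd=2.0,
            noise_corr_time_s=0.3,
            timing_jitter_frac=0.10,
            seed=101 + k,
        )
        for k in range(6)
    ]


@dataclass(frozen=True)
class MotionTrial:
    """One time-stamped reaching trial of the five recorded angles."""

    subject_id: str
    target_id: int
    repetition: int
    session: int
    times: np.ndarray  # (n,) seconds, uniform
    angles: np.ndarray  # (n, 5) degrees, ANGLE_COLUMNS order
    phase_samples: tuple[int, int, int, int] | None = field(
        default=None, compare=False
    )  # per-phase sample counts; None if unknown (e.g. read from CSV)

    @property
    def key(self) -> tuple:
        return (self.subject_id, self.target_id, self.repetition, self.session)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def validate(self, arm: ArmModel | None = None, grid: TargetGrid | None = None):
        t, a = np.asarray(self.times), np.asarray(self.angles)
        if a.shape != (len(t), 5):
            raise SchemaError(f"trial {self.key}: angles shape {a.shape}")
        if len(t) < 2 or np.any(np.diff(t) <= 0):
            raise SchemaError(f"trial {self.key}: times not strictly increasing")
        if np.max(np.abs(np.diff(t) - self.dt)) > 1e-6:
            raise SchemaError(f"trial {self.key}: non-uniform sampling interval")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(a))):
            raise SchemaError(f"trial {self.key}: non-finite values")
        if arm is not None and grid is not None:
            q = recorded_to_full(a[[0, -1]])
            tips = forward_kinematics(arm, q).fingertip
            dist = np.linalg.norm(tips - grid.center, axis=-1)
            if np.any(dist > 0.05):
                raise SchemaError(
                    f"trial {self.key}: endpoints {dist.round(3)} m from center"
                )


@dataclass
class MotionDataset:
    """A collection of motion trials plus task metadata."""

    trials: list[MotionTrial]
    provenance: str = "surrogate"  # surrogate | DRL | hybrid | AVG
    grid: TargetGrid | None = None
    timing: PhaseTiming | None = None

    def __post_init__(self):
        keys = [tr.key for tr in self.trials]
        if len(set(keys)) != len(keys):
            dup = [k for k in keys if keys.count(k) > 1][0]
            raise SchemaError(f"duplicate trial key {dup}")

    def __len__(self):
        return len(self.trials)

    @property
    def subject_ids(self) -> list[str]:
        return sorted({tr.subject_id for tr in self.trials})

    @property
    def dt(self) -> float:
        return self.trials[0].dt

    def validate(self, arm: ArmModel | None = None):
        if not self.trials:
            raise SchemaError("dataset has no trials")
        for tr in self.trials:
            tr.validate(arm=arm, grid=self.grid if arm is not None else None)
            if abs(tr.dt - self.dt) > 1e-9:
                raise SchemaError(f"trial {tr.key}: dt differs across dataset")

    def subset(
        self,
        subjects=None,
        targets=None,
        repetitions=None,
        sessions=None,
        provenance: str | None = None,
    ) -> "MotionDataset":
        """Filtered copy; each filter is an iterable of allowed values."""

        def keep(tr: MotionTrial) -> bool:
            return (
                (subjects is None or tr.subject_id in subjects)
                and (targets is None or tr.target_id in targets)
                and (repetitions is None or tr.repetition in repetitions)
                and (sessions is None or tr.session in sessions)
            )

        return MotionDataset(
            trials=[tr for tr in self.trials if keep(tr)],
            provenance=provenance or self.provenance,
            grid=self.grid,
            timing=self.timing,
        )

    def merge(self, other: "MotionDataset", provenance: str = "hybrid"):
        return MotionDataset(
            trials=self.trials + other.trials,
            provenance=provenance,
            grid=self.grid,
            timing=self.timing,
        )

    def to_frame(self) -> pd.DataFrame:
        chunks = []
        for tr in self.trials:
            df = pd.DataFrame(tr.angles, columns=list(ANGLE_COLUMNS))
            df.insert(0, "t", tr.times)
            df.insert(0, "session", tr.session)
            df.insert(0, "repetition", tr.repetition)
            df.insert(0, "target_id", tr.target_id)
            df.insert(0, "subject_id", tr.subject_id)
            chunks.append(df)
        return pd.concat(chunks, ignore_index=True)


def minimum_jerk_profile(tau):
    """Minimum-jerk position fraction s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5.

    Zero velocity and acceleration at both ends; peak normalized speed
    15/8 at tau = 1/2.
    """
    tau = np.asarray(tau, float)
    if np.any(tau < 0) or np.any(tau > 1):
        raise ValueError("tau must lie in [0, 1]")
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def _jittered_phase_samples(timing: PhaseTiming, frac: float, rng) -> tuple[int, ...]:
    counts = []
    for dur in timing.phase_durations:
        scale = 1.0 + (rng.uniform(-frac, frac) if frac > 0 else 0.0)
        counts.append(max(1, int(round(dur * scale / timing.dt))))
    return tuple(counts)


def _ou_noise(n: int, sd: float, corr_time: float, dt: float, rng) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path: sd ``sd``, correlation time ``corr_time``."""
    x = np.empty(n)
    x[0] = rng.normal(0.0, 1.0)
    rho = np.exp(-dt / corr_time)
    innov = rng.normal(0.0, 1.0, size=n - 1) * np.sqrt(1.0 - rho * rho)
    for k in range(1, n):
        x[k] = x[k - 1] * rho + innov[k - 1]
    return sd * x


def synthesize_trial(
    profile: SubjectProfile,
    arm: ArmModel,
    grid: TargetGrid,
    timing: PhaseTiming,
    target_id: int,
    repetition: int = 1,
    session: int = 1,
) -> MotionTrial:
    """One surrogate center-out-center trial.

    The fingertip follows straight center-target-center lines under
    minimum-jerk time scaling; joint angles come from swivel-resolved
    inverse kinematics at the subject's swivel angle, with palm down.
    Smooth OU noise (sd ``angle_noise_sd``) is added per recorded angle
    and per-phase durations are jittered by ``timing_jitter_frac``.
    Deterministic given (profile.seed, target, repetition, session).
    """
    rng = np.random.default_rng(
        [int(profile.seed), int(target_id), int(repetition), int(session)]
    )
    counts = _jittered_phase_samples(timing, profile.timing_jitter_frac, rng)
    n_reach, n_touch, n_return, n_wait = counts
    target = grid.target(target_id)

    segs = []
    tau = np.arange(n_reach) / n_reach
    segs.append(grid.center + minimum_jerk_profile(tau)[:, None] * (target - grid.center))
    segs.append(np.tile(target, (n_touch, 1)))
    tau = np.arange(n_return) / n_return
    segs.append(target + minimum_jerk_profile(tau)[:, None] * (grid.center - target))
    segs.append(np.tile(grid.center, (n_wait, 1)))
    path = np.concatenate(segs, axis=0)

    q = inverse_kinematics_swivel(arm, path, profile.swivel_deg, palm_down=True)
    angles = q[:, list(RECORDED_JOINTS)]

    n = len(path)
    if profile.angle_noise_sd >= 0:
        noise = np.stack(
            [
                _ou_noise(
                    n,
                    profile.angle_noise_sd,
                    profile.noise_corr_time_s,
                    timing.dt,
                    rng,
                )
                for _ in range(5)
            ],
            axis=1,
        )
        # Anchor the noise at the trial boundaries: the subject rests on
        # the center point at the start and end, so kinematic noise dies
        # out there (0.25 s linear ramps).
        ramp = max(1, int(round(0.25 / timing.dt)))
        k = np.arange(n, dtype=float)
        envelope = np.minimum(1.0, np.minimum(k / ramp, (n - 1 - k) / ramp))
        angles = angles + noise * envelope[:, None]

    return MotionTrial(
        subject_id=profile.subject_id,
        target_id=target_id,
        repetition=repetition,
        session=session,
        times=np.arange(n) * timing.dt,
        angles=angles,
        phase_samples=counts,
    )


def synthesize_subject(
    profile: SubjectProfile,
    arm: ArmModel,
    grid: TargetGrid,
    timing: PhaseTiming,
    repetitions: int = 4,
    sessions: int = 2,
) -> MotionDataset:
    """All trials of one subject: repetitions x targets x sessions."""
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    trials = [
        synthesize_trial(profile, arm, grid, timing, tid, rep, ses)
        for ses in range(1, sessions + 1)
        for rep in range(1, repetitions + 1)
        for tid in range(1, grid.n_targets + 1)
    ]
    return MotionDataset(trials=trials, provenance="surrogate", grid=grid, timing=timing)


def _nominal_phase_samples(timing: PhaseTiming) -> tuple[int, ...]:
    return tuple(int(round(d / timing.dt)) for d in timing.phase_durations)


def _resample_trial(tr: MotionTrial, timing: PhaseTiming) -> MotionTrial:
    """Map a trial onto the nominal time grid by per-phase linear interpolation.

    Phase boundaries come from the trial's recorded per-phase sample
    counts; for trials without them (CSV round-trips) the nominal phase
    proportions are assumed.
    """
    nominal = _nominal_phase_samples(timing)
    counts = tr.phase_samples
    if counts is None:
        scale = tr.n_samples / sum(nominal)
        counts = tuple(max(1, int(round(c * scale))) for c in nominal[:-1])
        counts = counts + (tr.n_samples - sum(counts),)
    if sum(counts) != tr.n_samples:
        raise SchemaError(f"trial {tr.key}: phase samples disagree with length")
    out = []
    start = 0
    for n_src, n_dst in zip(counts, nominal):
        seg = tr.angles[start : start + n_src]
        src = np.linspace(0.0, 1.0, n_src)
        dst = np.linspace(0.0, 1.0, n_dst)
        out.append(
            np.stack([np.interp(dst, src, seg[:, c]) for c in range(5)], axis=1)
        )
        start += n_src
    angles = np.concatenate(out, axis=0)
    return MotionTrial(
        subject_id=tr.subject_id,
        target_id=tr.target_id,
        repetition=tr.repetition,
        session=tr.session,
        times=np.arange(len(angles)) * timing.dt,
        angles=angles,
        phase_samples=nominal,
    )


def average_subjects(datasets: list[MotionDataset]) -> MotionDataset:
    """Pointwise cross-subject mean after per-phase time normalization.

    Every dataset must share the same (target, repetition, session)
    trial structure; the result carries subject id "AVG".
    """
    if not datasets:
        raise IncompatibleDatasetsError("no datasets given")
    timing = datasets[0].timing
    if timing is None:
        raise IncompatibleDatasetsError("datasets need timing metadata to average")

    def structure(ds):
        return sorted((tr.target_id, tr.repetition, tr.session) for tr in ds.trials)

    ref = structure(datasets[0])
    for ds in datasets[1:]:
        if structure(ds) != ref:
            raise IncompatibleDatasetsError("datasets have mismatched trial structure")

    by_key: dict[tuple, list[MotionTrial]] = {}
    for ds in datasets:
        for tr in ds.trials:
            by_key.setdefault((tr.target_id, tr.repetition, tr.session), []).append(tr)

    out = []
    for (tid, rep, ses), trs in sorted(by_key.items()):
        res = [_resample_trial(tr, timing) for tr in trs]
        mean = np.mean([r.angles for r in res], axis=0)
        out.append(
            MotionTrial(
                subject_id="AVG",
                target_id=tid,
                repetition=rep,
                session=ses,
                times=res[0].times,
                angles=mean,
                phase_samples=res[0].phase_samples,
            )
        )
    return MotionDataset(
        trials=out, provenance="AVG", grid=datasets[0].grid, timing=timing
    )


# -- CSV I/O -----------------------------------------------------------------

def write_dataset(dataset: MotionDataset, path) -> None:
    """Write the dataset as a flat CSV (schema in :data:`CSV_COLUMNS`)."""
    frame = dataset.to_frame()
    frame.to_csv(path, index=False, float_format="%.12g")


def _frame_to_dataset(frame: pd.DataFrame, provenance: str) -> MotionDataset:
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    trials = []
    grouped = frame.groupby(
        ["subject_id", "target_id", "repetition", "session"], sort=True
    )
    for (sid, tid, rep, ses), g in grouped:
        g = g.sort_values("t")
        tr = MotionTrial(
            subject_id=str(sid),
            target_id=int(tid),
            repetition=int(rep),
            session=int(ses),
            times=g["t"].to_numpy(float),
            angles=g[list(ANGLE_COLUMNS)].to_numpy(float),
        )
        tr.validate()
        trials.append(tr)
    return MotionDataset(trials=trials, provenance=provenance)


def read_dataset(path, provenance: str = "surrogate") -> MotionDataset:
    """Read and schema-validate a motion CSV written by :func:`write_dataset`."""
    try:
        frame = pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise SchemaError(f"cannot read motion CSV {path}: {exc}") from exc
    return _frame_to_dataset(frame, provenance)
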