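"""End-to-end scenarios comparing decoders trained on different data mixes.

Scenario "sufficient": for each surrogate subject, a decoder trained on
the averaged motion of the five other subjects (Human-Avg-Model) and a
decoder trained purely on the reinforcement-learned synthetic data
(DRL-Model) are both tested on the held-out subject's second session.

Scenario "limited": each subject contributes a single repetition towards
four targets (1, 3, 5, 7) to train a Human-Sparse-Model; the Hybrid-Model
additionally receives one synthetic repetition towards the remaining
four targets (2, 4, 6, 8).  Both are evaluated on all eight targets of
every other subject (cross-subject), and the percentage improvement of
hybrid over sparse is tabulated per training subject.

Session 1 is always training data, session 2 testing; no test subject's
trials ever enter a training set (asserted by trial-key intersection).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .drl import PolicyHandle, RewardWeights, clone_dataset, train_policy
from .evaluation import MetricsReport, compute_metrics
from .kinematics import ArmModel
from .predictor import (
    PredictorConfig,
    WindowConfig,
    predict_dataset,
    train_predictor,
)
from .sac import SACConfig
from .subjects import (
    MotionDataset,
    SubjectProfile,
    average_subjects,
    default_profiles,
    synthesize_subject,
)
from .task import PhaseTiming, TargetGrid, generate_target_grid

__all__ = [
    "ScenarioConfig",
    "ExperimentReport",
    "scenario_sufficient_data",
    "scenario_limited_data",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to run one scenario end-to-end."""

    scenario: str = "sufficient"  # "sufficient" | "limited"
    profiles: tuple[SubjectProfile, ...] = tuple(default_profiles())
    arm: ArmModel = ArmModel()
    grid: TargetGrid = field(default_factory=generate_target_grid)
    timing: PhaseTiming = PhaseTiming()
    reward_weights: RewardWeights = RewardWeights()
    sac: SACConfig = SACConfig()
    policy_steps: int = 200_000
    predictor: PredictorConfig = PredictorConfig()
    window: WindowConfig = WindowConfig()
    repetitions: int = 4
    sessions: int = 2
    sparse_human_targets: tuple[int, ...] = (1, 3, 5, 7)
    drl_fill_targets: tuple[int, ...] = (2, 4, 6, 8)
    test_repetitions: tuple[int, ...] | None = None  # None = all
    seed: int = 0

    def __post_init__(self):
        sparse, fill = set(self.sparse_human_targets), set(self.drl_fill_targets)
        if sparse & fill:
            raise ValueError("sparse and fill target sets must be disjoint")
        if not (sparse | fill) <= set(range(1, self.grid.n_targets + 1)):
            raise ValueError("target ids out of range")
        if len(self.profiles) < 2:
            raise ValueError("need at least two subject profiles")


@dataclass
class ExperimentReport:
    """Per-model metrics plus aggregate tables of one scenario run."""

    scenario: str
    summary: pd.DataFrame  # one row per (model, subject) with the key means
    metrics: dict[str, dict[str, MetricsReport]] = field(repr=False)
    improvement: pd.DataFrame | None = None  # limited scenario only
    meta: dict = field(default_factory=dict)

    def aggregate_means(self) -> pd.DataFrame:
        cols = [c for c in ("rmse_deg", "reaching_error_cm") if c in self.summary]
        return self.summary.groupby("model")[cols].mean()

    def to_json_dict(self) -> dict:
        out = {
            "scenario": self.scenario,
            "meta": self.meta,
            "summary": self.summary.to_dict(orient="records"),
            "aggregate_means": self.aggregate_means().reset_index().to_dict(
                orient="records"
            ),
            "metrics": {
                model: {subj: rep.to_json_dict() for subj, rep in per.items()}
                for model, per in self.metrics.items()
            },
        }
        if self.improvement is not None:
            out["improvement"] = self.improvement.to_dict(orient="records")
        return out

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(self.to_json_dict(), indent=1))
        self.summary.to_csv(out / "summary.csv", index=False)
        if self.improvement is not None:
            self.improvement.to_csv(out / "improvement.csv", index=False)


def _assert_disjoint(train: MotionDataset, test: MotionDataset):
    inter = {tr.key for tr in train.trials} & {tr.key for tr in test.trials}
    if inter:
        raise AssertionError(f"test trials leaked into training: {sorted(inter)[:3]}")


def _surrogate_datasets(cfg: ScenarioConfig) -> dict[str, MotionDataset]:
    return {
        p.subject_id: synthesize_subject(
            p, cfg.arm, cfg.grid, cfg.timing, cfg.repetitions, cfg.sessions
        )
        for p in cfg.profiles
    }


def _test_set(cfg: ScenarioConfig, ds: MotionDataset) -> MotionDataset:
    sub = ds.subset(sessions={min(2, cfg.sessions)})
    if cfg.test_repetitions is not None:
        sub = sub.subset(repetitions=set(cfg.test_repetitions))
    return sub


def _ensure_policy(cfg: ScenarioConfig, policy: PolicyHandle | None) -> PolicyHandle:
    if policy is not None:
        return policy
    return train_policy(
        cfg.arm,
        cfg.grid,
        cfg.timing,
        cfg.reward_weights,
        steps=cfg.policy_steps,
        seed=cfg.seed,
        sac_config=cfg.sac,
    )


def scenario_sufficient_data(
    cfg: ScenarioConfig, policy: PolicyHandle | None = None
) -> ExperimentReport:
    """Leave-one-subject-out comparison of Human-Avg and DRL decoders."""
    surrogates = _surrogate_datasets(cfg)
    policy = _ensure_policy(cfg, policy)
    drl_data = clone_dataset(
        policy, cfg.arm, cfg.grid, cfg.timing, repetitions=cfg.repetitions
    )
    # The synthetic training set must contain no human/surrogate trials.
    assert set(drl_data.subject_ids) == {"DRL"}
    drl_model = train_predictor(
        drl_data, cfg.predictor.scaled(seed=cfg.seed * 1000 + 1), cfg.window
    )

    metrics: dict[str, dict[str, MetricsReport]] = {"DRL-Model": {}, "Human-Avg-Model": {}}
    rows = []
    for i, profile in enumerate(cfg.profiles):
        held_out = profile.subject_id
        test = _test_set(cfg, surrogates[held_out])
        train_sets = [
            surrogates[p.subject_id].subset(sessions={1})
            for p in cfg.profiles
            if p.subject_id != held_out
        ]
        avg = average_subjects(train_sets)
        for ts in train_sets + [avg, drl_data]:
            _assert_disjoint(ts, test)
        avg_model = train_predictor(
            avg, cfg.predictor.scaled(seed=cfg.seed * 1000 + 10 + i), cfg.window
        )
        for model_name, model in (
            ("Human-Avg-Model", avg_model),
            ("DRL-Model", drl_model),
        ):
            rep = compute_metrics(
                predict_dataset(model, test), test, cfg.arm, cfg.grid
            )
            metrics[model_name][held_out] = rep
            rows.append(
                {
                    "model": model_name,
                    "subject_id": held_out,
                    "rmse_deg": rep.overall_rmse_deg,
                    "reaching_error_cm": rep.mean_reaching_error_cm,
                }
            )
    summary = pd.DataFrame(rows)
    return ExperimentReport(
        scenario="sufficient",
        summary=summary,
        metrics=metrics,
        meta={
            "policy_steps": policy.steps_trained,
            "policy_seed": policy.training_seed,
            "seed": cfg.seed,
            "n_subjects": len(cfg.profiles),
        },
    )


def scenario_limited_data(
    cfg: ScenarioConfig, policy: PolicyHandle | None = None
) -> ExperimentReport:
    """Cross-subject comparison of Human-Sparse and Hybrid decoders."""
    surrogates = _surrogate_datasets(cfg)
    policy = _ensure_policy(cfg, policy)
    drl_fill = clone_dataset(
        policy, cfg.arm, cfg.grid, cfg.timing, repetitions=1
    ).subset(targets=set(cfg.drl_fill_targets))

    metrics: dict[str, dict[str, MetricsReport]] = {
        "Human-Sparse-Model": {},
        "Hybrid-Model": {},
    }
    rows = []
    imp_rows = []
    for i, profile in enumerate(cfg.profiles):
        sid = profile.subject_id
        sparse_train = surrogates[sid].subset(
            sessions={1}, repetitions={1}, targets=set(cfg.sparse_human_targets)
        )
        hybrid_train = sparse_train.merge(drl_fill, provenance="hybrid")
        sparse_model = train_predictor(
            sparse_train, cfg.predictor.scaled(seed=cfg.seed * 1000 + 100 + i), cfg.window
        )
        hybrid_model = train_predictor(
            hybrid_train, cfg.predictor.scaled(seed=cfg.seed * 1000 + 200 + i), cfg.window
        )
        model_means = {}
        for model_name, model in (
            ("Human-Sparse-Model", sparse_model),
            ("Hybrid-Model", hybrid_model),
        ):
            per_subject_rmse = []
            for other in cfg.profiles:
                if other.subject_id == sid:
                    continue
                test = _test_set(cfg, surrogates[other.subject_id])
                _assert_disjoint(sparse_train, test)
                _assert_disjoint(hybrid_train, test)
                rep = compute_metrics(
                    predict_dataset(model, test), test, cfg.arm, cfg.grid
                )
                metrics[model_name][f"{sid}->{other.subject_id}"] = rep
                per_subject_rmse.append(rep.overall_rmse_deg)
            mean_rmse = float(np.mean(per_subject_rmse))
            model_means[model_name] = mean_rmse
            rows.append(
                {"model": model_name, "subject_id": sid, "rmse_deg": mean_rmse}
            )
        sparse_m = model_means["Human-Sparse-Model"]
        hybrid_m = model_means["Hybrid-Model"]
        imp_rows.append(
            {
                "subject_id": sid,
                "sparse_rmse_deg": sparse_m,
                "hybrid_rmse_deg": hybrid_m,
                "improvement_pct": (sparse_m - hybrid_m) / sparse_m * 100.0,
            }
        )
    summary = pd.DataFrame(rows)
    improvement = pd.DataFrame(imp_rows)
    return ExperimentReport(
        scenario="limited",
        summary=summary,
        metrics=metrics,
        improvement=improvement,
        meta={
            "policy_steps": policy.steps_trained,
            "policy_seed": policy.training_seed,
            "seed": cfg.seed,
            "n_subjects": len(cfg.profiles),
            "sparse_targets": list(cfg.sparse_human_targets),
            "fill_targets": list(cfg.drl_fill_targets),
        },
    )
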