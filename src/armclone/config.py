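"""YAML configuration for the whole pipeline.

A config file has optional sections [arm], [grid], [timing], [reward],
[sac], [predictor], [window], [subjects] and [scenario]; every omitted
key falls back to the package defaults, so ``{}`` is a valid config.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .drl import RewardWeights
from .experiments import ScenarioConfig
from .kinematics import ArmModel
from .predictor import PredictorConfig, WindowConfig
from .sac import SACConfig
from .subjects import SubjectProfile, default_profiles
from .task import PhaseTiming, generate_target_grid

__all__ = ["load_config", "scenario_config_from_dict", "config_hash"]


def _profiles_from(entries) -> tuple[SubjectProfile, ...]:
    return tuple(SubjectProfile(**e) for e in entries)


def scenario_config_from_dict(d: dict) -> ScenarioConfig:
    d = d or {}
    arm = ArmModel.from_dict(d.get("arm", {}))
    grid_d = d.get("grid", {})
    grid = generate_target_grid(
        center=grid_d.get("center", (0.35, 0.0, -0.25)),
        diameter=grid_d.get("diameter_m", 0.5),
        n_targets=grid_d.get("n_targets", 8),
    )
    timing = PhaseTiming(**d.get("timing", {}))
    reward = RewardWeights(**d.get("reward", {}))
    sac_d = dict(d.get("sac", {}))
    if "hidden" in sac_d:
        sac_d["hidden"] = tuple(sac_d["hidden"])
    sac = SACConfig(**sac_d)
    predictor = PredictorConfig(**d.get("predictor", {}))
    window = WindowConfig(**d.get("window", {}))
    profiles = (
        _profiles_from(d["subjects"]) if d.get("subjects") else tuple(default_profiles())
    )
    sc = dict(d.get("scenario", {}))
    for yaml_key, attr in (
        ("sparse_targets", "sparse_human_targets"),
        ("fill_targets", "drl_fill_targets"),
    ):
        if yaml_key in sc:
            sc[attr] = tuple(sc.pop(yaml_key))
    if "test_repetitions" in sc and sc["test_repetitions"] is not None:
        sc["test_repetitions"] = tuple(sc["test_repetitions"])
    return ScenarioConfig(
        arm=arm,
        grid=grid,
        timing=timing,
        reward_weights=reward,
        sac=sac,
        predictor=predictor,
        window=window,
        profiles=profiles,
        **sc,
    )


def load_config(path) -> ScenarioConfig:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    with open(p) as fh:
        data = yaml.safe_load(fh) or {}
    return scenario_config_from_dict(data)


def config_hash(d: dict | None) -> str:
    """Stable short hash of a config dict, for run manifests."""
    return hashlib.sha256(
        json.dumps(d or {}, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
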