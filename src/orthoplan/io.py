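"""Configuration, schemas, structured I/O and the end-to-end pipeline.

Data formats are JSON / JSON-lines / CSV / YAML only.  Every pipeline run
writes a manifest (package version, seeds, config hash, stage outputs)
sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import yaml

from . import __version__
from .agent import EncoderSpec, RandomActor, TrainConfig
from .cohort import (CohortConfig, PatientRecord, cohort_feature_table,
                     read_cohort, record_from_dict, record_to_dict,
                     sample_cohort, write_cohort)
from .env import EnvConfig
from .metrics import compare_policies
from .planner import PlannerResults, TreatmentPlanner, _config_hash
from .rewards import TaskWeights
from .explain import attribute, explain_trajectory, fit_surrogate, render_report
from .state import feature_names

log = logging.getLogger("orthoplan")


def setup_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter(
        "%(asctime)s level=%(levelname)s module=%(name)s %(message)s",
        datefmt="%Y-%m-%dT%H:%M:%S%z"))
    root = logging.getLogger("orthoplan")
    root.handlers[:] = [handler]
    root.setLevel(level.upper())


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


# ----------------------------------------------------------------------
# patient record files
# ----------------------------------------------------------------------
def write_patient(record: PatientRecord, path) -> None:
    Path(path).write_text(json.dumps(record_to_dict(record), indent=2) + "\n")


def read_patient(path) -> PatientRecord:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed patient JSON at {path}: {exc}") from exc
    return record_from_dict(data)


# ----------------------------------------------------------------------
# run configuration
# ----------------------------------------------------------------------
@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    env: EnvConfig = field(default_factory=EnvConfig)
    weights: TaskWeights = field(default_factory=TaskWeights)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval_episodes: int = 20
    explain_top_k: int = 10
    seed: int = 0
    out_dir: str = "runs/default"
    log_level: str = "INFO"

    def apply_seed(self) -> None:
        self.cohort.seed = self.seed
        self.env.seed = self.seed
        self.train.seed = self.seed


_SUBCONFIGS = {"cohort": CohortConfig, "env": EnvConfig, "weights": TaskWeights,
               "train": TrainConfig}


def config_to_dict(config: RunConfig) -> Dict:
    d = dataclasses.asdict(config)
    return d


def config_from_dict(d: Dict) -> RunConfig:
    kwargs: Dict = {}
    for key, value in d.items():
        if key in _SUBCONFIGS:
            cls = _SUBCONFIGS[key]
            names = {f.name for f in dataclasses.fields(cls)}
            unknown = set(value) - names
            if unknown:
                raise ValueError(f"unknown keys in '{key}' config: {sorted(unknown)}")
            if key == "train" and "encoder" in value and isinstance(value["encoder"], dict):
                value = dict(value, encoder=EncoderSpec(**value["encoder"]))
            if key == "train" and "weights" in value and isinstance(value["weights"], dict):
                value = dict(value, weights=TaskWeights(**value["weights"]))
            kwargs[key] = cls(**value)
        else:
            kwargs[key] = value
    allowed = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(kwargs) - allowed
    if unknown:
        raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"configuration file not found: {p}")
    data = yaml.safe_load(p.read_text()) or {}
    return config_from_dict(data)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


# ----------------------------------------------------------------------
# episode export
# ----------------------------------------------------------------------
def episode_to_jsonl(episode, path) -> None:
    """One JSON object per treatment step: state digest, action, reward, info."""
    with open(path, "w") as fh:
        for i, st in enumerate(episode.steps):
            a = st.action
            fh.write(json.dumps({
                "step": i,
                "state": {"ANB_deg": st.state.skeletal.anb,
                          "phase": st.state.treatment_status.phase,
                          "facial_harmony": st.state.soft_tissue.facial_harmony,
                          "relapse_risk": st.state.treatment_status.relapse_risk,
                          "elapsed_months": st.state.treatment_status.elapsed_months},
                "action": {"sagittal_mm": a.sagittal_mm, "vertical_mm": a.vertical_mm,
                           "transverse_mm": a.transverse_mm, "force_g": a.force_g,
                           "appliance": a.appliance,
                           "soft_tissue_technique": a.soft_tissue_technique,
                           "timing": a.timing, "phase_decision": a.phase_decision,
                           "interval_weeks": a.interval_weeks},
                "reward": dict(zip(("functional", "aesthetic", "efficiency", "stability"),
                                   st.reward.as_array().tolist())),
                "info": {k: v for k, v in st.info.items() if k != "clips"},
            }) + "\n")


# ----------------------------------------------------------------------
# pipeline
# ----------------------------------------------------------------------
def run_pipeline(config: RunConfig) -> Path:
    """simulate-cohort -> train -> evaluate -> explain, with a manifest.

    Any stage failure aborts with a stage-named error; partial outputs are
    retained next to a ``FAILED`` marker.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.apply_seed()
    manifest: Dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config.cohort, config.env, config.train),
        "stages": {},
    }
    save_config(config, out / "config.yaml")

    stage = "simulate-cohort"
    try:
        log.info("stage=%s n=%d seed=%d", stage, config.cohort.n, config.cohort.seed)
        records = sample_cohort(config.cohort)
        write_cohort(records, out / "cohort.jsonl")
        cohort_feature_table(records[: min(len(records), 100)],
                             seed=config.seed).to_csv(out / "cohort_features.csv")
        manifest["stages"][stage] = {"outputs": ["cohort.jsonl", "cohort_features.csv"],
                                     "n_records": len(records)}

        stage = "train"
        log.info("stage=%s steps=%d", stage, config.train.total_steps)
        planner = TreatmentPlanner(records, env_config=config.env,
                                   weights=config.weights, train_config=config.train)
        results = planner.fit()
        results.save(out / "checkpoint.npz")
        import pandas as pd
        pd.DataFrame(results.log).to_csv(out / "training_log.csv", index=False)
        manifest["stages"][stage] = {"outputs": ["checkpoint.npz", "training_log.csv"],
                                     "final_return": results.log[-1]["mean_return"]}

        stage = "evaluate"
        log.info("stage=%s episodes=%d", stage, config.eval_episodes)
        from .agent import SACPolicyActor
        task = planner.make_task()
        comparison = compare_policies(
            planner.make_task,
            {"trained": SACPolicyActor(results.params),
             "random": RandomActor(task.cont_dim, task.cat_sizes)},
            n_episodes=config.eval_episodes, seed=config.seed,
            weights=config.weights, gamma=config.train.gamma)
        comparison.table.to_csv(out / "evaluation.csv")
        pw = {f"{a}_vs_{b}": v for (a, b), v in comparison.pairwise.items()}
        (out / "evaluation_pairwise.json").write_text(json.dumps(pw, indent=2))
        manifest["stages"][stage] = {"outputs": ["evaluation.csv",
                                                 "evaluation_pairwise.json"]}

        stage = "explain"
        log.info("stage=%s", stage)
        rec = records[-1]
        episode = results.simulate(rec, seed=config.seed)
        episode_to_jsonl(episode, out / "plan_trajectory.jsonl")
        tx = explain_trajectory(episode, config.weights)
        text, doc = render_report(tx, "specialist")
        (out / "explanation_trajectory.md").write_text(text)
        (out / "explanation_trajectory.json").write_text(json.dumps(doc, indent=2))

        state = episode.steps[0].state
        obs0 = planner.normalizer(state.feature_vector())
        w = config.weights

        def qmodel(X):
            from .agent import q_vector
            fwd = results.params.policy.forward(np.atleast_2d(obs0))
            t, probs, _, _, _ = results.params.policy.sample(fwd, None, deterministic=True)
            a = np.concatenate([t] + list(probs), axis=1)
            A = np.repeat(a, np.atleast_2d(X).shape[0], axis=0)
            q = q_vector(np.atleast_2d(X), A, results.params)
            return np.atleast_2d(q) @ w.as_array()

        att = attribute(qmodel, obs0, np.zeros_like(obs0), n_samples=16,
                        seed=config.seed, feature_names=feature_names())
        text, doc = render_report(att, "specialist", top_k=config.explain_top_k)
        (out / "explanation_attribution.md").write_text(text)
        (out / "explanation_attribution.json").write_text(json.dumps(doc, indent=2))
        manifest["stages"][stage] = {"outputs": [
            "plan_trajectory.jsonl", "explanation_trajectory.md",
            "explanation_trajectory.json", "explanation_attribution.md",
            "explanation_attribution.json"]}
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise StageError(stage, exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
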