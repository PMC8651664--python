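"""End-to-end pipeline: cohort -> augmentation -> ARTE -> agents -> report.

Every stage writes a text artifact (CSV/JSON/JSONL) stamped with the
config hash and seed; a rerun with ``resume=True`` reuses artifacts that
already exist, so the pipeline is resumable stage by stage.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import agent as agent_mod
from . import arte as arte_mod
from . import augmentation as aug_mod
from . import cohort as cohort_mod
from . import evaluation as eval_mod
from .config import RunConfig, config_hash

log = logging.getLogger("qdrlart")

__all__ = ["run_pipeline"]


def _stamp(path: Path, payload: dict, chash: str, seed: int) -> None:
    payload = {"config_hash": chash, "seed": seed, **payload}
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def _write_csv(df: pd.DataFrame, path: Path, chash: str, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={chash} seed={seed}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def _augmented_to_records(frame: pd.DataFrame) -> list:
    records = []
    for i, row in frame.iterrows():
        d = row.to_dict()
        d["patient_id"] = f"S{i:05d}"
        records.append(d)
    df = pd.DataFrame(records)[cohort_mod.COHORT_COLUMNS]
    return cohort_mod.frame_to_records(df)


def run_pipeline(config: RunConfig, resume: bool = False) -> dict:
    """Run simulate-cohort -> augment -> fit-arte -> train -> recommend ->
    evaluate.  Returns the evaluation report; artifacts land in
    ``config.outdir``."""
    chash = config_hash(config)
    seed = config.seed
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    grid = config.qdecision.grid()

    def stage(name):
        log.info("stage %-16s (config %s)", name, chash)

    # stage seeds derived from the global seed
    cohort_cfg = config.cohort
    cohort_cfg.seed = seed
    gan_cfg = config.augmentation
    gan_cfg.seed = seed + 1
    train_cfg = config.agent
    train_cfg.seed = seed + 2
    train_cfg.backend = config.qdecision.backend
    train_cfg.shots = config.qdecision.shots

    cohort_path = out / "cohort.csv"
    stage("simulate-cohort")
    if resume and cohort_path.exists():
        records = cohort_mod.read_cohort(cohort_path)
    else:
        try:
            records = cohort_mod.generate_cohort(cohort_cfg)
        except Exception as exc:
            raise RuntimeError(f"stage simulate-cohort failed (config {chash}): {exc}") from exc
        _write_csv(cohort_mod.records_to_frame(records), cohort_path, chash, seed)

    stage("augment")
    aug_path = out / "augmented.csv"
    if resume and aug_path.exists():
        aug_frame = pd.read_csv(aug_path, comment="#")
    else:
        try:
            aug_frame, _ = aug_mod.fit_and_generate(records, gan_cfg)
        except Exception as exc:
            raise RuntimeError(f"stage augment failed (config {chash}): {exc}") from exc
        flagged = aug_frame.copy()
        flagged["is_synthetic"] = 1
        _write_csv(flagged, aug_path, chash, seed)
    train_records = records + _augmented_to_records(aug_frame.drop(
        columns=[c for c in ("is_synthetic",) if c in aug_frame.columns]))

    stage("fit-arte")
    arte_path = out / "arte.json"
    rb = config.arte.radbio
    if resume and arte_path.exists():
        blob = json.loads(arte_path.read_text())
        transition = arte_mod.TransitionModel.from_dict(blob["transition"])
        estimator = arte_mod.OutcomeEstimator.from_dict(blob["estimator"])
    else:
        try:
            transition = arte_mod.TransitionModel(
                hidden=config.arte.transition_hidden, seed=seed,
                dose_range=(grid.d_min, grid.d_max))
            transition.fit(train_records, epochs=config.arte.transition_epochs)
            estimator = arte_mod.fit_outcome_estimator(
                train_records, config.arte.estimator, rb)
        except Exception as exc:
            raise RuntimeError(f"stage fit-arte failed (config {chash}): {exc}") from exc
        _stamp(arte_path, {"transition": transition.to_dict(),
                           "estimator": estimator.to_dict()}, chash, seed)

    def env_factory():
        return arte_mod.Arte(transition, estimator, rb, max_steps=config.arte.max_steps)

    stage("train")
    agents = []
    ckpt_paths = [out / f"qnet_member{m}.json" for m in range(train_cfg.ensemble_size)]
    if resume and all(p.exists() for p in ckpt_paths):
        agents = [agent_mod.DQNAgent.from_dict(json.loads(p.read_text())["agent"])
                  for p in ckpt_paths]
    else:
        try:
            agents, all_traces = agent_mod.train_ensemble(
                train_records, env_factory, train_cfg, grid=grid)
        except Exception as exc:
            raise RuntimeError(f"stage train failed (config {chash}): {exc}") from exc
        for m, (agent, path) in enumerate(zip(agents, ckpt_paths)):
            _stamp(path, {"member": m, "agent": agent.to_dict()}, chash, seed)
        with open(out / "traces.jsonl", "w") as fh:
            fh.write(json.dumps({"config_hash": chash, "seed": seed}) + "\n")
            for traces in all_traces:
                for tr in traces:
                    text = tr.to_jsonl()
                    if text:
                        fh.write(text + "\n")

    stage("recommend")
    rec_rows = []
    recommendations = {}
    for r in records:
        rec = agent_mod.recommend(agents, r.state_mid)
        recommendations[r.patient_id] = rec.mean_dose
        rec_rows.append({
            "patient_id": r.patient_id,
            "ai_dose": rec.mean_dose,
            "sem": rec.sem,
            "q_confidence": float(np.mean(rec.member_q)),
            "clinical_dose": r.clinical_dose,
            "lc": r.lc, "rp2": r.rp2,
        })
    _write_csv(pd.DataFrame(rec_rows), out / "recommendations.csv", chash, seed)

    stage("evaluate")
    report = eval_mod.evaluate_cohort(records, recommendations)
    _stamp(out / "report.json", {"report": report}, chash, seed)
    return report
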