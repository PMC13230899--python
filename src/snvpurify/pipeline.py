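"""End-to-end pipeline: simulate -> extract -> train -> correct -> evaluate.

Each stage writes its outputs under the configured output root together
with a config-hash sentinel; re-running with an unchanged config skips
stages whose outputs already exist (stage-level resume). The run manifest
records the timestamp, the resolved config and every artifact path. The
global seed fully determines every stage's outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import features as ft
from . import simulate as sim
from .config import PipelineConfig, config_to_dict, dump_config
from .model import CorrectionModel, ModelConfig
from .train import fit

logger = logging.getLogger(__name__)

STAGES = ("simulate", "extract", "train", "correct", "evaluate")


def _config_hash(cfg: PipelineConfig, stage: str) -> str:
    blob = json.dumps({"stage": stage, "config": config_to_dict(cfg)}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_done(root: Path, stage: str, h: str) -> bool:
    sentinel = root / f".{stage}.hash"
    return sentinel.exists() and sentinel.read_text().strip() == h


def _mark_done(root: Path, stage: str, h: str) -> None:
    (root / f".{stage}.hash").write_text(h + "\n")


def _log_stage(root: Path, stage: str, payload: dict) -> None:
    entry = {"stage": stage, "time": time.strftime("%Y-%m-%dT%H:%M:%S"), **payload}
    with open(root / "pipeline.log.jsonl", "a") as fh:
        fh.write(json.dumps(entry) + "\n")
    logger.info("stage %s: %s", stage, payload)


def run_pipeline(cfg: PipelineConfig, resume: bool = True) -> dict:
    """Run all five stages; returns the artifact manifest.

    The cohort is split up front: a held-out fraction (``holdout_fraction``,
    stratified arbitrarily by sample order after seeded shuffling) never
    enters training and is the set every evaluation metric is computed on.
    """
    root = Path(cfg.output_root)
    root.mkdir(parents=True, exist_ok=True)
    dump_config(cfg, root / "config_resolved.yaml")
    manifest: dict = {"output_root": str(root),
                      "started": time.strftime("%Y-%m-%dT%H:%M:%S")}

    # stage 1: simulate ------------------------------------------------------
    h = _config_hash(cfg, "simulate")
    sim_dir = root / "simulated"
    if resume and _stage_done(root, "simulate", h) and (sim_dir / "truth.tsv").exists():
        _log_stage(root, "simulate", {"skipped": True})
    else:
        cohort = sim.simulate_cohort(cfg.simulation)
        sim.write_cohort(cohort, sim_dir)
        _mark_done(root, "simulate", h)
        _log_stage(root, "simulate", {"n_samples": cfg.simulation.n_samples})
    manifest["simulated"] = str(sim_dir)
    truths = sim.read_truth_table(sim_dir / "truth.tsv")

    # stage 2: extract -------------------------------------------------------
    h = _config_hash(cfg, "extract")
    feat_path = root / "features.tsv"
    if resume and _stage_done(root, "extract", h) and feat_path.exists():
        _log_stage(root, "extract", {"skipped": True})
    else:
        tracks = {name: ft.read_bed(sim_dir / f"{name}.bed", name)
                  for name in ft.TRACK_NAMES}
        fsets = {}
        for t in truths:
            records = ft.read_vcf(sim_dir / "vcf" / f"{t.sample_id}.vcf")
            fsets[t.sample_id] = ft.build_feature_groups(records, tracks)
        ft.feature_table(fsets).to_csv(feat_path, sep="\t")
        _log_stage(root, "extract", {"n_samples": len(fsets)})
        _mark_done(root, "extract", h)
    manifest["features"] = str(feat_path)

    feat_df = pd.read_csv(feat_path, sep="\t", index_col="sample_id")
    fsets = ft.feature_sets_from_table(feat_df)
    truth_by_id = {t.sample_id: t for t in truths}
    ids = sorted(fsets)

    # held-out split (seeded shuffle; never seen in training)
    rng = np.random.default_rng([cfg.seed, 31])
    order = rng.permutation(len(ids))
    n_hold = max(1, int(round(cfg.holdout_fraction * len(ids))))
    hold_ids = sorted(ids[i] for i in order[:n_hold])
    train_ids = sorted(ids[i] for i in order[n_hold:])

    # stage 3: train ---------------------------------------------------------
    h = _config_hash(cfg, "train")
    ckpt = root / "model.ckpt.json"
    if resume and _stage_done(root, "train", h) and ckpt.exists():
        _log_stage(root, "train", {"skipped": True})
        model = CorrectionModel.load(ckpt)
    else:
        model = CorrectionModel(cfg.model)
        model, history = fit(
            model,
            [fsets[i] for i in train_ids],
            [truth_by_id[i].true_snv_count for i in train_ids],
            [truth_by_id[i].true_purity for i in train_ids],
            cfg.train,
        )
        model.save(ckpt)
        with open(root / "train_history.json", "w") as fh:
            json.dump({"train_loss": history.train_loss,
                       "val_loss": history.val_loss,
                       "best_epoch": history.best_epoch}, fh)
        _log_stage(root, "train", {"epochs": len(history.train_loss),
                                   "best_epoch": history.best_epoch})
        _mark_done(root, "train", h)
    manifest["checkpoint"] = str(ckpt)

    # stage 4: correct -------------------------------------------------------
    h = _config_hash(cfg, "correct")
    corrected_path = root / "corrected.tsv"
    if resume and _stage_done(root, "correct", h) and corrected_path.exists():
        _log_stage(root, "correct", {"skipped": True})
    else:
        preds = model.predict([fsets[i] for i in ids])
        pd.DataFrame({"sample_id": ids, "corrected_count": preds}).to_csv(
            corrected_path, sep="\t", index=False)
        _log_stage(root, "correct", {"n_samples": len(ids)})
        _mark_done(root, "correct", h)
    manifest["corrected"] = str(corrected_path)

    # stage 5: evaluate (held-out samples only) ------------------------------
    h = _config_hash(cfg, "evaluate")
    eval_dir = root / "evaluation"
    corrected = pd.read_csv(corrected_path, sep="\t").set_index("sample_id")
    report = ev.build_report(
        sample_ids=hold_ids,
        purity=[truth_by_id[i].true_purity for i in hold_ids],
        actual=[truth_by_id[i].true_snv_count for i in hold_ids],
        raw=[truth_by_id[i].raw_snv_count for i in hold_ids],
        corrected=[float(corrected.loc[i, "corrected_count"]) for i in hold_ids],
        correlations=ft.intra_group_correlation([fsets[i] for i in hold_ids]),
    )
    manifest["evaluation"] = ev.write_report(report, eval_dir,
                                             figures=cfg.evaluate.figures)
    _log_stage(root, "evaluate", {"n_holdout": len(hold_ids)})
    _mark_done(root, "evaluate", h)
    manifest["holdout_ids"] = hold_ids

    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
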