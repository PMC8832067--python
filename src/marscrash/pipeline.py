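"""End-to-end composition: simulate -> preprocess -> train -> evaluate
-> analyze, with a manifest linking every artifact to its inputs."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import List, Optional

import numpy as np

from . import crash_analysis, evaluation, io, pilot, preprocess
from .io import RunConfig
from .predictors import build_model, predict, train

log = logging.getLogger("marscrash")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir, force: bool = False) -> Path:
    """Run every stage into ``out_dir``; stages whose outputs already
    exist are reused unless ``force``.  Returns the artifact directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}

    # --- simulate -----------------------------------------------------
    trials_dir = out / "trials"
    if force or not trials_dir.exists():
        log.info("simulate: %d pilots x %d trials", config.n_pilots,
                 config.trials_per_pilot)
        cohort = pilot.make_cohort(config.n_pilots, config.difficulty_spread,
                                   seed=config.seed)
        trials = pilot.simulate_cohort(cohort, config.sim,
                                       config.trials_per_pilot,
                                       seed=config.seed)
        io.write_trials(trials, trials_dir)
    else:
        log.info("simulate: reusing %s", trials_dir)
        trials = io.read_trials(trials_dir)
    manifest["stages"]["simulate"] = {
        "n_trials": len(trials),
        "n_crashes": int(sum(len(t.crash_times) for t in trials)),
    }

    # --- preprocess ---------------------------------------------------
    windows_path = out / "windows.h5"
    episodes = preprocess.extract_all_episodes(trials)
    if force or not windows_path.exists():
        log.info("preprocess: %d episodes", len(episodes))
        windows = preprocess.make_all_windows(
            episodes, config.window_ms, config.advance_ms, config.stride_steps)
        io.save_windows(windows, windows_path)
    else:
        log.info("preprocess: reusing %s", windows_path)
        windows = io.load_windows(windows_path)
    split = preprocess.split_episodes([e.episode_id for e in episodes],
                                      config.train_fraction, seed=config.seed)
    train_ids = {e for e, s in split.items() if s == preprocess.TRAIN}
    tr_mask = np.isin(windows.episode_id, sorted(train_ids))
    train_w, test_w = windows.subset(tr_mask), windows.subset(~tr_mask)
    std = preprocess.Standardizer.fit(train_w)
    train_w, test_w = std.transform(train_w), std.transform(test_w)
    manifest["stages"]["preprocess"] = {
        "n_episodes": len(episodes), "n_windows": len(windows),
        "n_train_windows": len(train_w), "n_test_windows": len(test_w),
        "positive_fraction": float(windows.y.mean()),
    }

    # --- cross-validated training ------------------------------------
    folds = preprocess.assign_folds(sorted(train_ids), k=config.n_folds,
                                    seed=config.seed)
    report, artifacts = evaluation.cross_validate(
        train_w, folds, config.model, config.target_recall,
        return_models=True)
    (out / "reports").mkdir(exist_ok=True)
    (out / "reports" / "cv_report.json").write_text(
        json.dumps(report.to_dict(), indent=1))
    manifest["stages"]["evaluate"] = report.to_dict()

    # --- final test-set evaluation with the best fold's model ---------
    best_model = artifacts[report.best_fold][0]
    test_preds = predict(best_model, test_w)
    test_auc = evaluation.auc(test_preds)
    test_prec, thr = evaluation.precision_at_recall(test_preds,
                                                    config.target_recall)
    manifest["stages"]["test"] = {"auc": test_auc, "precision": test_prec,
                                  "threshold": thr}

    # --- crash analysis ----------------------------------------------
    region = crash_analysis.compute_recoverable_region(config.sim)
    sav = crash_analysis.savable_fraction(trials, region, config.advance_ms)
    analysis = {
        "misclassification_by_position":
            crash_analysis.misclassification_by_position(
                test_preds, thr, crash_boundary=config.sim.crash_boundary),
        "djd_rate_by_prediction_type":
            crash_analysis.djd_rate_by_prediction_type(
                test_preds, trials, config.advance_ms, thr),
        "savability": {"offsets_ms": sav.offsets_ms,
                       "percent_savable": sav.as_percent(),
                       "n_crashes": sav.n_crashes},
    }
    (out / "reports" / "analysis.json").write_text(
        json.dumps(analysis, indent=1))
    manifest["stages"]["analyze"] = analysis["savability"]

    for p in ("windows.h5",):
        manifest.setdefault("hashes", {})[p] = _sha256(out / p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
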