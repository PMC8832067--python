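"""Threshold-free and recall-first metrics, and grouped cross-validation.

AUC is computed as the pair-counting probability that a random crash
sample outscores a random non-crash sample (ties count one half) — the
Mann–Whitney rank statistic, not a curve integration.  Model selection
uses precision at a fixed high recall (default 0.95): among decision
thresholds achieving the target recall, the largest (fewest predicted
positives) is chosen and its precision reported, written P@0.95R.
Cross-validation is 10-fold with episode-level grouping so windows of
one episode never straddle a fold boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

from .predictors import ModelSpec, PredictionRecord, build_model, predict, train
from .preprocess import WindowSet


def _scores_labels(predictions: Sequence[PredictionRecord]
                   ) -> Tuple[np.ndarray, np.ndarray]:
    if predictions and isinstance(predictions[0], PredictionRecord):
        s = np.array([p.score for p in predictions], dtype=float)
        y = np.array([p.label for p in predictions], dtype=int)
        return s, y
    scores, labels = predictions  # (scores, labels) pair also accepted
    return np.asarray(scores, dtype=float), np.asarray(labels, dtype=int)


def auc(predictions) -> float:
    """Probability a random positive outscores a random negative (ties 1/2)."""
    s, y = _scores_labels(predictions)
    pos = y == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(s)  # average ranks implement the tie-1/2 convention
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def precision_at_recall(predictions, target_recall: float = 0.95
                        ) -> Tuple[float, float]:
    """Precision at the largest threshold achieving recall >= target.

    Thresholds are swept over the observed score values (predicted crash
    iff score >= threshold; step-function convention, no interpolation).
    Returns (precision, threshold).
    """
    if not 0.0 < target_recall <= 1.0:
        raise ValueError("target_recall must be in (0, 1]")
    s, y = _scores_labels(predictions)
    n_pos = int((y == 1).sum())
    if n_pos == 0:
        raise ValueError("no positive samples; recall undefined")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted == 1)
    fp = np.cumsum(y_sorted == 0)
    # candidate cuts: last index of each distinct score value
    last_of_value = np.flatnonzero(np.diff(s_sorted, append=-np.inf) != 0)
    recall = tp[last_of_value] / n_pos
    ok = np.flatnonzero(recall >= target_recall - 1e-12)
    i = last_of_value[ok[0]]  # largest qualifying threshold
    precision = tp[i] / (tp[i] + fp[i])
    return float(precision), float(s_sorted[i])


def confusion_at(predictions, threshold: float) -> Dict[str, int]:
    """Confusion counts at a threshold (predicted crash iff score >= it)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    s, y = _scores_labels(predictions)
    pred = s >= threshold
    return {
        "TP": int(np.sum(pred & (y == 1))),
        "FP": int(np.sum(pred & (y == 0))),
        "FN": int(np.sum(~pred & (y == 1))),
        "TN": int(np.sum(~pred & (y == 0))),
    }


def prediction_types(predictions, threshold: float) -> np.ndarray:
    """Per-sample label in {"TP","FP","FN","TN"} at a threshold."""
    s, y = _scores_labels(predictions)
    pred = s >= threshold
    out = np.empty(len(s), dtype="U2")
    out[pred & (y == 1)] = "TP"
    out[pred & (y == 0)] = "FP"
    out[~pred & (y == 1)] = "FN"
    out[~pred & (y == 0)] = "TN"
    return out


@dataclass
class EvalReport:
    """Per-fold and aggregate cross-validation metrics."""

    family: str
    window_ms: float
    advance_ms: float
    target_recall: float
    fold_auc: List[float] = field(default_factory=list)
    fold_precision: List[float] = field(default_factory=list)
    fold_threshold: List[float] = field(default_factory=list)
    skipped_folds: List[int] = field(default_factory=list)
    best_fold: int = -1

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.fold_auc, ddof=1)) if len(self.fold_auc) > 1 else 0.0

    @property
    def mean_precision(self) -> float:
        return float(np.mean(self.fold_precision))

    @property
    def sd_precision(self) -> float:
        return (float(np.std(self.fold_precision, ddof=1))
                if len(self.fold_precision) > 1 else 0.0)

    def to_dict(self) -> dict:
        return {
            "family": self.family, "window_ms": self.window_ms,
            "advance_ms": self.advance_ms, "target_recall": self.target_recall,
            "fold_auc": self.fold_auc, "fold_precision": self.fold_precision,
            "fold_threshold": self.fold_threshold,
            "mean_auc": self.mean_auc, "sd_auc": self.sd_auc,
            "mean_precision": self.mean_precision,
            "sd_precision": self.sd_precision,
            "best_fold": self.best_fold, "skipped_folds": self.skipped_folds,
        }


def cross_validate(windows: WindowSet, fold_assignment: Dict[int, int],
                   spec: ModelSpec, target_recall: float = 0.95,
                   return_models: bool = False):
    """k-fold CV with one model trained per held-out fold.

    ``fold_assignment`` maps episode id -> fold index (episode-grouped).
    Folds whose held-out part lacks one of the classes are skipped with
    a warning entry.  Returns the EvalReport (and per-fold artifacts if
    ``return_models``): the best fold by AUC is exposed for final-test
    use.
    """
    folds = sorted(set(fold_assignment.values()))
    if len(folds) < 2:
        raise ValueError("need at least 2 folds")
    ep_fold = np.array([fold_assignment[int(e)] for e in windows.episode_id])
    report = EvalReport(family=spec.family, window_ms=windows.window_ms,
                        advance_ms=windows.advance_ms,
                        target_recall=target_recall)
    artifacts = []
    for fold in folds:
        val_mask = ep_fold == fold
        tr, va = windows.subset(~val_mask), windows.subset(val_mask)
        if len(np.unique(va.y)) < 2 or len(np.unique(tr.y)) < 2:
            report.skipped_folds.append(fold)
            continue
        model = build_model(spec, windows.X.shape[1:])
        model, hist = train(model, tr, va, spec)
        preds = predict(model, va)
        report.fold_auc.append(auc(preds))
        p, thr = precision_at_recall(preds, target_recall)
        report.fold_precision.append(p)
        report.fold_threshold.append(thr)
        if return_models:
            artifacts.append((model, hist, preds))
    if not report.fold_auc:
        raise ValueError("every fold was single-class; cannot evaluate")
    report.best_fold = int(np.argmax(report.fold_auc))
    if return_models:
        return report, artifacts
    return report
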