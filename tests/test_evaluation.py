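"""Metric oracles: pair-counting AUC, precision-at-recall sweep, grouped
cross-validation plumbing, and the difficulty trend in advance_ms."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from marscrash.evaluation import (auc, confusion_at, cross_validate,
                                  precision_at_recall, prediction_types)
from marscrash.predictors import ModelSpec
from marscrash import preprocess

import helpers

score_sets = st.lists(
    st.tuples(st.sampled_from([0.0, 0.1, 0.25, 0.5, 0.5, 0.75, 0.9, 1.0]),
              st.integers(0, 1)),
    min_size=4, max_size=60).filter(
        lambda rows: 0 < sum(y for _, y in rows) < len(rows))


class TestAUC:
    def test_perfect_separation(self):
        assert auc(([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])) == 1.0

    def test_spec_example(self):
        # 4 positive-negative pairs, 3 won by positives
        assert auc(([0.8, 0.6, 0.4, 0.2], [1, 0, 1, 0])) == 0.75

    def test_all_ties(self):
        assert auc(([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc(([0.5, 0.6], [1, 1]))

    @given(rows=score_sets)
    def test_matches_bruteforce_paircount(self, rows):
        s = [r[0] for r in rows]
        y = [r[1] for r in rows]
        assert auc((s, y)) == pytest.approx(
            helpers.auc_bruteforce(s, y), abs=1e-12)


class TestPrecisionAtRecall:
    def test_spec_example(self):
        p, thr = precision_at_recall(
            ([0.9, 0.8, 0.4, 0.7, 0.2], [1, 1, 1, 0, 0]), 0.95)
        assert p == 0.75 and thr == 0.4

    def test_perfect_separation(self):
        p, _ = precision_at_recall(([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]), 0.95)
        assert p == 1.0

    def test_target_one_vs_half(self):
        preds = ([0.9, 0.8, 0.4, 0.7, 0.2, 0.6], [1, 1, 1, 0, 0, 0])
        p_hi, _ = precision_at_recall(preds, 1.0)
        p_lo, _ = precision_at_recall(preds, 0.5)
        assert p_hi <= p_lo

    def test_validation(self):
        with pytest.raises(ValueError):
            precision_at_recall(([0.5], [0]), 0.95)
        with pytest.raises(ValueError):
            precision_at_recall(([0.5, 0.6], [0, 1]), 0.0)

    @given(rows=score_sets)
    def test_matches_exhaustive_sweep(self, rows):
        s = [r[0] for r in rows]
        y = [r[1] for r in rows]
        for target in (0.5, 0.8, 0.95, 1.0):
            got = precision_at_recall((s, y), target)
            want = helpers.precision_sweep_bruteforce(s, y, target)
            assert got[0] == pytest.approx(want[0], abs=1e-12)
            assert got[1] == pytest.approx(want[1], abs=1e-12)

    @given(rows=score_sets)
    def test_max_precision_monotone_in_target_recall(self, rows):
        # the qualifying-threshold set shrinks as the target grows, so the
        # best achievable precision can only fall
        s = [r[0] for r in rows]
        y = [r[1] for r in rows]
        values = [helpers.max_precision_at_recall(s, y, t)
                  for t in (0.25, 0.5, 0.75, 0.9, 1.0)]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))


class TestConfusion:
    def test_partition_and_extremes(self):
        s = np.array([0.1, 0.6, 0.4, 0.8, 0.3])
        y = np.array([0, 1, 1, 1, 0])
        c = confusion_at((s, y), 0.5)
        assert sum(c.values()) == 5
        assert c == {"TP": 2, "FP": 0, "FN": 1, "TN": 2}
        hi = confusion_at((s, y), 0.9)
        assert hi["TP"] == 0 and hi["FP"] == 0
        lo = confusion_at((s, y), 0.0)
        assert lo["FN"] == 0  # recall 1 at threshold <= min score

    def test_prediction_types_partition(self):
        s = np.array([0.1, 0.6, 0.4, 0.8])
        y = np.array([0, 1, 0, 1])
        types = prediction_types((s, y), 0.5)
        assert types.tolist() == ["TN", "TP", "TN", "TP"]


class TestCrossValidation:
    def test_k2_toy_run(self, small_windows):
        std = preprocess.Standardizer.fit(small_windows)
        w = std.transform(small_windows)
        folds = preprocess.assign_folds(
            sorted({int(e) for e in w.episode_id}), k=2, seed=0)
        rep = cross_validate(w, folds, ModelSpec(family="LINEAR",
                                                 seed=0).scaled(max_epochs=4))
        assert len(rep.fold_auc) == 2
        assert all(0.0 <= a <= 1.0 for a in rep.fold_auc)
        assert rep.best_fold == int(np.argmax(rep.fold_auc))
        d = rep.to_dict()
        assert d["mean_auc"] == pytest.approx(np.mean(rep.fold_auc))
        assert d["sd_auc"] == pytest.approx(np.std(rep.fold_auc, ddof=1))

    def test_single_class_fold_skipped(self):
        from test_predictors import synthetic_windows
        w = synthetic_windows(n=200, n_episodes=10)
        w.y[w.episode_id >= 8] = 0  # folds holding only negatives
        folds = {e: (0 if e < 4 else (1 if e < 8 else 2)) for e in range(10)}
        rep = cross_validate(w, folds, ModelSpec(family="LINEAR",
                                                 seed=0).scaled(max_epochs=2))
        assert rep.skipped_folds == [2]
        assert len(rep.fold_auc) == 2

    def test_needs_two_folds(self, small_windows):
        with pytest.raises(ValueError):
            cross_validate(small_windows,
                           {int(e): 0 for e in small_windows.episode_id},
                           ModelSpec(family="LINEAR").scaled())


class TestAdvanceDifficultyTrend:
    def test_auc_decreases_with_advance(self, small_episodes):
        # predicting further ahead is strictly harder: MLP validation AUC
        # falls as advance_ms grows (see docs/methods.md on why raw
        # precision is not the right monotone statistic on synthetic data)
        aucs = []
        for adv in (300.0, 600.0, 1000.0):
            w = preprocess.make_all_windows(small_episodes, 1000.0, adv,
                                            stride_steps=2)
            ids = sorted({int(e) for e in w.episode_id})
            split = preprocess.split_episodes(ids, 0.8, seed=0)
            mask = np.isin(w.episode_id,
                           sorted(e for e, s in split.items()
                                  if s == preprocess.TRAIN))
            std = preprocess.Standardizer.fit(w.subset(mask))
            tw, vw = std.transform(w.subset(mask)), std.transform(w.subset(~mask))
            from marscrash.predictors import build_model, predict, train
            spec = ModelSpec(family="MLP", seed=0).scaled()
            m = build_model(spec, w.X.shape[1:])
            m, _ = train(m, tw, vw, spec)
            aucs.append(auc(predict(m, vw)))
        assert aucs[0] > aucs[1] > aucs[2]
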