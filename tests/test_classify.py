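"""Cross-validation, metrics, McNemar, and weight-map tests."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from lbpbrain import (CVConfig, SelectionCriteria, compute_metrics,
                      correctness_by_subject, fit_selection, mcnemar,
                      rank_auc, run_cv, weight_map)


def _dataset(rng, n_per_class=12, grid=(6, 6, 6), shift=0.0):
    X = rng.standard_normal((2 * n_per_class, 1, *grid))
    y = np.array([1] * n_per_class + [-1] * n_per_class)
    X[y == 1, 0, 1:3, 1:3, 1:3] += shift
    return X, y


def test_run_cv_is_deterministic():
    rng = np.random.default_rng(80)
    X, y = _dataset(rng, shift=1.0)
    cfg = CVConfig(n_folds=4, n_repeats=2, seed=3)
    crit = SelectionCriteria(alpha=0.05)
    validity = np.ones(X.shape[2:], bool)
    a = run_cv(X, y, validity, crit, cfg)
    b = run_cv(X, y, validity, crit, cfg)
    for fa, fb in zip(a.folds, b.folds):
        np.testing.assert_array_equal(fa.test_idx, fb.test_idx)
        np.testing.assert_array_equal(fa.y_pred, fb.y_pred)
        np.testing.assert_allclose(fa.scores, fb.scores)
    c = run_cv(X, y, validity, crit, CVConfig(n_folds=4, n_repeats=2, seed=4))
    assert any(not np.array_equal(fa.test_idx, fc.test_idx)
               for fa, fc in zip(a.folds, c.folds))


def test_each_repeat_partitions_all_subjects_with_stratification():
    rng = np.random.default_rng(81)
    X, y = _dataset(rng, shift=1.0)
    cfg = CVConfig(n_folds=4, n_repeats=3, seed=0)
    res = run_cv(X, y, np.ones(X.shape[2:], bool), SelectionCriteria(alpha=0.05), cfg)
    for rep in range(cfg.n_repeats):
        frs = res.repeat_folds(rep)
        assert len(frs) == cfg.n_folds
        all_idx = np.concatenate([f.test_idx for f in frs])
        assert sorted(all_idx) == list(range(y.size))
        for f in frs:
            assert (y[f.test_idx] == 1).sum() == (y[f.test_idx] == -1).sum()


def test_strong_effect_classified_perfectly():
    rng = np.random.default_rng(82)
    X, y = _dataset(rng, shift=6.0)
    res = run_cv(X, y, np.ones(X.shape[2:], bool), SelectionCriteria(alpha=0.001),
                 CVConfig(n_folds=4, n_repeats=2, seed=1))
    m = compute_metrics(res)
    assert m.mean_accuracy == 1.0
    assert m.mean_auc == 1.0
    assert m.mean_sensitivity == 1.0 and m.mean_specificity == 1.0


def test_pure_noise_stays_near_chance():
    rng = np.random.default_rng(83)
    X, y = _dataset(rng, n_per_class=14, shift=0.0)
    res = run_cv(X, y, np.ones(X.shape[2:], bool), SelectionCriteria(alpha=0.05),
                 CVConfig(n_folds=4, n_repeats=5, seed=2))
    m = compute_metrics(res)
    assert 0.25 <= m.mean_accuracy <= 0.75
    assert 0.25 <= m.mean_auc <= 0.75


def test_empty_selection_falls_back_to_majority():
    rng = np.random.default_rng(84)
    X, y = _dataset(rng, shift=0.0)
    res = run_cv(X, y, np.ones(X.shape[2:], bool),
                 SelectionCriteria(alpha=1e-12),
                 CVConfig(n_folds=4, n_repeats=1, seed=0))
    for f in res.folds:
        assert f.flat_index.size == 0
        assert (f.scores == 0).all()
        assert len(set(f.y_pred)) == 1


def test_per_fold_selection_never_sees_test_subjects():
    # direct audit: recompute the selection from the training subjects only
    # and require the recorded per-fold model to match it exactly
    rng = np.random.default_rng(85)
    X, y = _dataset(rng, shift=1.2)
    validity = np.ones(X.shape[2:], bool)
    crit = SelectionCriteria(alpha=0.1)
    res = run_cv(X, y, validity, crit, CVConfig(n_folds=4, n_repeats=2, seed=9))
    for f in res.folds:
        train_idx = np.setdiff1d(np.arange(y.size), f.test_idx)
        ref = fit_selection(X[train_idx], y[train_idx], validity, crit)
        np.testing.assert_array_equal(f.flat_index, ref.flat_index)


def test_label_permutation_stays_at_chance():
    # end-to-end leakage check: with permuted labels nothing generalizes
    rng = np.random.default_rng(86)
    X, y = _dataset(rng, n_per_class=14, shift=3.0)
    y_perm = rng.permutation(y)
    res = run_cv(X, y_perm, np.ones(X.shape[2:], bool),
                 SelectionCriteria(alpha=0.05),
                 CVConfig(n_folds=4, n_repeats=5, seed=5))
    m = compute_metrics(res)
    assert 0.2 <= m.mean_accuracy <= 0.8


def test_rank_auc_against_reference():
    rng = np.random.default_rng(87)
    scores = rng.standard_normal(200)
    labels = np.where(rng.standard_normal(200) > 0, 1, -1)
    assert rank_auc(scores, labels) == pytest.approx(
        roc_auc_score(labels, scores))
    y = np.array([1, 1, -1, -1])
    assert rank_auc(np.array([2.0, 1.5, 1.0, 0.5]), y) == 1.0
    assert rank_auc(np.array([0.5, 1.0, 1.5, 2.0]), y) == 0.0
    assert rank_auc(np.zeros(4), y) == 0.5
    with pytest.raises(ValueError):
        rank_auc(np.zeros(3), np.array([1, 1, 1]))


def test_mcnemar_hand_values():
    # b=20, c=5: z = 15 / 5 = 3.0
    a = np.array([True] * 20 + [False] * 5 + [True] * 10)
    b = np.array([False] * 20 + [True] * 5 + [True] * 10)
    r = mcnemar(a, b)
    assert (r.b, r.c) == (20, 5)
    assert r.z == pytest.approx(3.0)
    assert r.p == pytest.approx(2 * stats.norm.sf(3.0))
    rc = mcnemar(a, b, continuity=True)
    assert rc.z == pytest.approx(14.0 / 5.0)
    # symmetric disagreement gives z = 0
    sym = mcnemar(np.array([True, False]), np.array([False, True]))
    assert sym.z == 0.0 and sym.p == 1.0
    same = mcnemar(np.array([True, True]), np.array([True, True]))
    assert same.z == 0.0
    # two-sided 95% significance threshold on z
    crit = stats.norm.ppf(0.975)
    assert crit == pytest.approx(1.960, abs=5e-4)
    assert mcnemar(np.array([True] * 9 + [False]),
                   np.array([False] * 9 + [False])).z > crit


def test_correctness_by_subject_covers_everyone():
    rng = np.random.default_rng(88)
    X, y = _dataset(rng, shift=5.0)
    res = run_cv(X, y, np.ones(X.shape[2:], bool), SelectionCriteria(alpha=0.01),
                 CVConfig(n_folds=4, n_repeats=1, seed=0))
    corr = correctness_by_subject(res, repeat=0)
    assert corr.shape == (y.size,)
    assert corr.all()  # strong effect: everyone classified correctly
    with pytest.raises(ValueError):
        correctness_by_subject(res, repeat=1)


def test_weight_map_conventions():
    rng = np.random.default_rng(89)
    X, y = _dataset(rng, shift=5.0)
    res = run_cv(X, y, np.ones(X.shape[2:], bool), SelectionCriteria(alpha=0.001),
                 CVConfig(n_folds=4, n_repeats=1, seed=0))
    wm = weight_map(res, repeat=0)
    assert len(wm.planes) == res.n_planes
    for plane in wm.planes:
        assert plane.min() >= 0.0 and plane.max() <= 1.0
    stacked = np.stack(wm.planes)
    assert (stacked[~wm.ever_selected] == 0).all()
    assert stacked[wm.ever_selected].max() == 1.0
    with pytest.raises(ValueError):
        weight_map(res, repeat=2)


def test_cv_config_validation():
    with pytest.raises(ValueError):
        CVConfig(n_folds=1)
    with pytest.raises(ValueError):
        CVConfig(n_repeats=0)
    with pytest.raises(ValueError):
        CVConfig(svm_c=0.0)
    rng = np.random.default_rng(90)
    X, y = _dataset(rng, n_per_class=3)
    with pytest.raises(ValueError):
        run_cv(X, y, np.ones(X.shape[2:], bool), cfg=CVConfig(n_folds=4))
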