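"""Linear-SVM classification with repeated cross-validation.

The estimator is a soft-margin SVM with a linear kernel on feature vectors
built by the two-step selection, with labels +1 (patient) / -1 (control).
To keep the performance estimate unbiased, *both* the voxelwise t-test
selection and the per-feature standardization are refit inside every
training fold; test subjects never contribute to either. Stratified 10-fold
cross-validation is repeated (default 30 times) and metrics are averaged
over repeats.

Classifier pairs are compared with McNemar's test on discordant
correctness counts: z = |b - c| / sqrt(b + c), significant at z > 1.960
(two-sided 95%). Linear-SVM weights are back-projected to template space as
per-voxel average absolute weights, min-max normalized to [0, 1].
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .selection import SelectionCriteria, _as_feature_array, apply_selection, fit_selection

__all__ = [
    "CVConfig",
    "FoldResult",
    "CVResult",
    "Metrics",
    "McNemarResult",
    "WeightMap",
    "run_cv",
    "compute_metrics",
    "rank_auc",
    "mcnemar",
    "weight_map",
    "correctness_by_subject",
]


@dataclasses.dataclass(frozen=True)
class CVConfig:
    """Cross-validation and SVM settings.

    Defaults: stratified 10-fold, 30 repeats, linear SVM with C=1, per-fold
    train-fit z-scoring on. All randomness (fold shuffling) derives from
    ``seed``.
    """

    n_folds: int = 10
    n_repeats: int = 30
    stratified: bool = True
    seed: int = 0
    svm_c: float = 1.0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError(f"n_folds must be >= 2, got {self.n_folds}")
        if self.n_repeats < 1:
            raise ValueError(f"n_repeats must be >= 1, got {self.n_repeats}")
        if self.svm_c <= 0:
            raise ValueError(f"svm_c must be positive, got {self.svm_c}")


@dataclasses.dataclass
class FoldResult:
    """One fitted fold: test predictions/scores plus the fitted model.

    ``flat_index`` and ``weights`` describe the fold's linear model in the
    selection's deterministic feature order (weights in standardized feature
    space when standardization is on). ``flat_index`` is empty when the fold
    selected no voxels; the fold then predicts the training majority class
    with score 0.
    """

    repeat: int
    fold: int
    test_idx: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray
    flat_index: np.ndarray
    weights: np.ndarray
    intercept: float


@dataclasses.dataclass
class CVResult:
    folds: list[FoldResult]
    labels: np.ndarray
    subject_ids: list[str]
    n_planes: int
    grid_shape: tuple[int, int, int]
    config: CVConfig

    @property
    def n_repeats(self) -> int:
        return self.config.n_repeats

    def repeat_folds(self, repeat: int) -> list[FoldResult]:
        return [f for f in self.folds if f.repeat == repeat]


def run_cv(feature_images, labels: Sequence[int], validity: np.ndarray,
           criteria: Optional[SelectionCriteria] = None,
           cfg: Optional[CVConfig] = None,
           subject_ids: Optional[Sequence[str]] = None) -> CVResult:
    """Repeated stratified k-fold CV with per-fold two-step selection.

    ``feature_images`` is coercible to (n_subjects, n_planes, *grid). Each
    repeat draws a fresh stratified partition from a seed derived from
    ``cfg.seed``; within each fold, selection and standardization are fit on
    the training subjects only, a linear SVM is trained, and test subjects
    receive the sign of the decision score (score 0 counts as +1).
    """
    if criteria is None:
        criteria = SelectionCriteria()
    if cfg is None:
        cfg = CVConfig()
    X = _as_feature_array(feature_images)
    y = np.asarray(labels)
    if subject_ids is None:
        subject_ids = [f"s{i:03d}" for i in range(y.size)]
    class_counts = [int((y == c).sum()) for c in (+1, -1)]
    if min(class_counts) < cfg.n_folds:
        raise ValueError(
            f"need >= n_folds={cfg.n_folds} subjects per class for stratification, "
            f"got {class_counts}")

    root = np.random.SeedSequence(cfg.seed)
    repeat_seeds = root.generate_state(cfg.n_repeats, dtype=np.uint32)

    folds: list[FoldResult] = []
    for rep in range(cfg.n_repeats):
        splitter = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True,
                                   random_state=int(repeat_seeds[rep]))
        for k, (train_idx, test_idx) in enumerate(splitter.split(np.zeros(y.size), y)):
            fr = _fit_fold(X, y, train_idx, test_idx, validity, criteria, cfg)
            fr.repeat, fr.fold = rep, k
            folds.append(fr)

    return CVResult(folds=folds, labels=y, subject_ids=list(subject_ids),
                    n_planes=X.shape[1], grid_shape=tuple(X.shape[2:]), config=cfg)


def _fit_fold(X, y, train_idx, test_idx, validity, criteria, cfg) -> FoldResult:
    model = fit_selection(X[train_idx], y[train_idx], validity, criteria)
    y_true = y[test_idx]
    if model.n_selected == 0:
        # no voxel survived selection: fall back to the training majority
        maj = 1 if (y[train_idx] == 1).sum() >= (y[train_idx] == -1).sum() else -1
        return FoldResult(repeat=-1, fold=-1, test_idx=np.asarray(test_idx),
                          y_true=y_true,
                          y_pred=np.full(y_true.size, maj),
                          scores=np.zeros(y_true.size),
                          flat_index=model.flat_index,
                          weights=np.zeros(0), intercept=0.0)

    tr = np.stack([apply_selection(model, X[i]) for i in train_idx])
    te = np.stack([apply_selection(model, X[i]) for i in test_idx])
    if cfg.standardize:
        mu = tr.mean(axis=0)
        sd = tr.std(axis=0)
        sd[sd == 0] = 1.0
        tr = (tr - mu) / sd
        te = (te - mu) / sd
    svm = SVC(kernel="linear", C=cfg.svm_c)
    svm.fit(tr, y[train_idx])
    # sklearn orders classes [-1, +1]; positive decision score means +1
    scores = svm.decision_function(te)
    y_pred = np.where(scores >= 0, 1, -1)
    return FoldResult(repeat=-1, fold=-1, test_idx=np.asarray(test_idx),
                      y_true=y_true, y_pred=y_pred, scores=scores,
                      flat_index=model.flat_index,
                      weights=svm.coef_[0].copy(),
                      intercept=float(svm.intercept_[0]))


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank formulation (ties get half credit)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclasses.dataclass
class Metrics:
    """Per-repeat metrics, their means, and pooled-over-repeats variants.

    ``per_repeat`` pools each repeat's test predictions (each subject is
    tested exactly once per repeat). ``pooled_*`` aggregate every prediction
    across all repeats instead of averaging per-repeat values; both
    summaries are reported because repeated-CV results can be pooled either
    way.
    """

    per_repeat: pd.DataFrame
    mean_accuracy: float
    mean_sensitivity: float
    mean_specificity: float
    mean_auc: float
    pooled_accuracy: float
    pooled_auc: float
    roc_curves: list[tuple[np.ndarray, np.ndarray]]


def _rates(y_true, y_pred):
    pos = y_true == 1
    neg = y_true == -1
    acc = float((y_pred == y_true).mean())
    sens = float((y_pred[pos] == 1).mean()) if pos.any() else np.nan
    spec = float((y_pred[neg] == -1).mean()) if neg.any() else np.nan
    return acc, sens, spec


def compute_metrics(result: CVResult) -> Metrics:
    """Accuracy/sensitivity/specificity/ROC/AUC per repeat plus means."""
    rows = []
    rocs = []
    all_true, all_pred, all_scores = [], [], []
    for rep in range(result.n_repeats):
        frs = result.repeat_folds(rep)
        if not frs:
            raise ValueError("empty CV result")
        y_true = np.concatenate([f.y_true for f in frs])
        y_pred = np.concatenate([f.y_pred for f in frs])
        scores = np.concatenate([f.scores for f in frs])
        if scores.size != y_true.size:
            raise ValueError("missing decision scores")
        acc, sens, spec = _rates(y_true, y_pred)
        auc = rank_auc(scores, y_true)
        fpr, tpr, _ = roc_curve(y_true, scores)
        rocs.append((fpr, tpr))
        rows.append({"repeat": rep, "accuracy": acc, "sensitivity": sens,
                     "specificity": spec, "auc": auc})
        all_true.append(y_true)
        all_pred.append(y_pred)
        all_scores.append(scores)
    df = pd.DataFrame(rows)
    y_true = np.concatenate(all_true)
    y_pred = np.concatenate(all_pred)
    scores = np.concatenate(all_scores)
    return Metrics(per_repeat=df,
                   mean_accuracy=float(df["accuracy"].mean()),
                   mean_sensitivity=float(df["sensitivity"].mean()),
                   mean_specificity=float(df["specificity"].mean()),
                   mean_auc=float(df["auc"].mean()),
                   pooled_accuracy=float((y_pred == y_true).mean()),
                   pooled_auc=rank_auc(scores, y_true),
                   roc_curves=rocs)


@dataclasses.dataclass
class McNemarResult:
    """Discordant counts and the normal-approximation z of McNemar's test."""

    b: int
    c: int
    z: float
    p: float


def mcnemar(correct_a: Sequence[bool], correct_b: Sequence[bool],
            continuity: bool = False) -> McNemarResult:
    """McNemar comparison of two classifiers on shared subjects.

    ``b`` counts subjects classifier A got right and B wrong; ``c`` the
    reverse. z = |b - c| / sqrt(b + c) (optionally with a -1 continuity
    correction on the numerator), two-sided normal p. b = c = 0 gives z = 0.
    """
    a = np.asarray(correct_a, dtype=bool)
    bb = np.asarray(correct_b, dtype=bool)
    if a.shape != bb.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {bb.shape}")
    b = int(np.sum(a & ~bb))
    c = int(np.sum(~a & bb))
    if b + c == 0:
        z = 0.0
    else:
        num = abs(b - c) - (1.0 if continuity else 0.0)
        z = max(num, 0.0) / np.sqrt(b + c)
    p = float(2.0 * stats.norm.sf(z))
    return McNemarResult(b=b, c=c, z=float(z), p=p)


def correctness_by_subject(result: CVResult, repeat: int = 0) -> np.ndarray:
    """Per-subject correctness booleans from one designated repeat, in
    subject order (each subject is tested exactly once per repeat)."""
    n = result.labels.size
    out = np.zeros(n, dtype=bool)
    seen = np.zeros(n, dtype=bool)
    for f in result.repeat_folds(repeat):
        out[f.test_idx] = f.y_pred == f.y_true
        seen[f.test_idx] = True
    if not seen.all():
        raise ValueError(f"repeat {repeat} does not cover all subjects")
    return out


@dataclasses.dataclass
class WeightMap:
    """Average absolute linear-SVM weights back-projected to the grid.

    One real volume per plane; values min-max normalized to [0, 1] over the
    voxels selected in at least one fold, zero elsewhere. A constant
    non-zero weight field maps to 1 (degenerate min-max convention).
    """

    planes: list[np.ndarray]
    ever_selected: np.ndarray


def weight_map(result: CVResult, repeat: int = 0) -> WeightMap:
    """Build the weight map of one repeat (mean |w| over its folds)."""
    frs = result.repeat_folds(repeat)
    if not frs:
        raise ValueError(f"no folds recorded for repeat {repeat}")
    size = result.n_planes * int(np.prod(result.grid_shape))
    acc = np.zeros(size, dtype=np.float64)
    ever = np.zeros(size, dtype=bool)
    for f in frs:
        if f.weights.size != f.flat_index.size:
            raise ValueError("weight map requires a linear kernel with per-feature weights")
        acc[f.flat_index] += np.abs(f.weights)
        ever[f.flat_index] = True
    acc /= len(frs)

    norm = np.zeros(size, dtype=np.float64)
    if ever.any():
        vals = acc[ever]
        lo, hi = vals.min(), vals.max()
        if hi > lo:
            norm[ever] = (vals - lo) / (hi - lo)
        else:
            norm[ever] = 1.0
    shaped = norm.reshape(result.n_planes, *result.grid_shape)
    ever_shaped = ever.reshape(result.n_planes, *result.grid_shape)
    return WeightMap(planes=[shaped[i] for i in range(result.n_planes)],
                     ever_selected=ever_shaped)
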