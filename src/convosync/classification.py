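"""Dyad-aware nested cross-validated linear SVM with permutation testing.

Classifies each *individual* as a member of a mixed (autistic +
non-autistic) or non-autistic dyad from the per-task feature table.  The
linear L2-regularised, L2-loss (squared-hinge) SVM is combined with:

* scaling of every feature to [-1, 1] and pruning of zero-variance
  features, both learned on training rows only,
* hyperplane (class) weighting inversely proportional to class frequencies
  to compensate the unbalanced design,
* a repeated, nested, stratified, *dyad-integral* cross-validation: both
  members of a dyad always share a fold, and per-fold class counts stay
  within one dyad of the global ratio.  Default structure: outer loop 7
  folds x 10 permutations, inner loop 10 folds x 1 permutation,
* inner-loop selection of the SVM penalty C by balanced accuracy and a
  post-hoc ROC-based (Youden J) shift of the decision threshold learned on
  inner out-of-fold scores,
* per-individual aggregation over outer permutations (mean decision score,
  majority-vote label) and a dyad-level label-permutation test of the
  balanced accuracy that keeps the CV structure intact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.svm import LinearSVC

from convosync.errors import ConfigError, ValidationError
from convosync.io_formats import FEATURE_COLUMNS, TASKS, get_logger

__all__ = [
    "FeatureMatrix",
    "CvPlan",
    "ClassifierReport",
    "DEFAULT_C_GRID",
    "build_feature_matrix",
    "make_cv_plan",
    "fit_predict_nested",
    "balanced_accuracy",
    "label_permutation_test",
]

logger = get_logger(__name__)

POSITIVE_LABEL = "mixed"
NEGATIVE_LABEL = "non_autistic"

#: SVM penalty grid searched by the inner loop
DEFAULT_C_GRID = tuple(2.0 ** k for k in range(-6, 7))


@dataclass
class FeatureMatrix:
    """Individuals x features design matrix with dyad bookkeeping.

    ``y`` codes the positive class (mixed dyad membership) as 1.  Both
    members of a dyad share ``dyad_ids`` entry and label.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    participant_ids: list[str]
    dyad_ids: list[str]

    @property
    def dyads(self) -> list[str]:
        seen: dict[str, None] = {}
        for d in self.dyad_ids:
            seen.setdefault(d)
        return list(seen)

    def dyad_labels(self) -> np.ndarray:
        rows = {d: self.y[i] for i, d in enumerate(self.dyad_ids)}
        return np.asarray([rows[d] for d in self.dyads])


def build_feature_matrix(
    feature_table: pd.DataFrame,
    dyad_types: dict[str, str],
    task_mode: str = "concat",
) -> FeatureMatrix:
    """Assemble the classifier design matrix from a per-task feature table.

    ``task_mode="concat"`` concatenates the per-task feature blocks (the
    default: 2 tasks x 15 features = 30 columns, dyadic values repeated for
    both dyad members); ``"mean"`` averages over tasks instead.
    Individuals lacking a task are excluded with a logged warning.
    """
    if task_mode not in ("concat", "mean"):
        raise ConfigError(f"unknown task_mode {task_mode!r}")
    df = feature_table.copy()
    rows = []
    for pid, sub in df.groupby("participant_id", sort=True):
        tasks_present = set(sub["task"])
        if not set(TASKS) <= tasks_present:
            logger.warning(
                "excluding %s: missing task(s) %s", pid, sorted(set(TASKS) - tasks_present)
            )
            continue
        dyad = sub["dyad_id"].iloc[0]
        if dyad not in dyad_types:
            raise ValidationError(f"no dyad type for dyad {dyad!r}")
        per_task = {
            task: sub[sub["task"] == task].iloc[0][FEATURE_COLUMNS].to_numpy(dtype=float)
            for task in TASKS
        }
        if task_mode == "concat":
            vec = np.concatenate([per_task[task] for task in TASKS])
        else:
            vec = np.mean([per_task[task] for task in TASKS], axis=0)
        rows.append((pid, dyad, dyad_types[dyad], vec))
    if not rows:
        raise ValidationError("no individual has complete features")
    if task_mode == "concat":
        names = [f"{feat}__{task}" for task in TASKS for feat in FEATURE_COLUMNS]
    else:
        names = list(FEATURE_COLUMNS)
    X = np.vstack([vec for *_, vec in rows])
    # median-impute residual missing values (e.g. undefined adaptation)
    for j in range(X.shape[1]):
        col = X[:, j]
        bad = ~np.isfinite(col)
        if bad.any():
            med = np.nanmedian(col)
            X[bad, j] = med if math.isfinite(med) else 0.0
    y = np.asarray([1 if lab == POSITIVE_LABEL else 0 for _, _, lab, _ in rows])
    return FeatureMatrix(
        X=X,
        y=y,
        feature_names=names,
        participant_ids=[pid for pid, *_ in rows],
        dyad_ids=[d for _, d, *_ in rows],
    )


# ---------------------------------------------------------------------------
# cross-validation plan


@dataclass
class CvPlan:
    """Stratified dyad-level fold assignments for the nested CV.

    ``outer_assignments[p, d]`` is the outer test fold of dyad ``d`` in
    outer permutation ``p``.  Inner splits are derived deterministically
    from ``inner_seed`` inside each outer training partition.
    """

    dyad_ids: list[str]
    outer_assignments: np.ndarray  # (n_outer_perms, n_dyads)
    n_outer_folds: int
    n_inner_folds: int
    inner_seed: int

    @property
    def n_outer_perms(self) -> int:
        return int(self.outer_assignments.shape[0])


def _stratified_folds(labels: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Dyad-level stratified fold assignment: round-robin within each class."""
    folds = np.empty(labels.size, dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        offset = int(rng.integers(n_folds))
        for i, d in enumerate(idx):
            folds[d] = (offset + i) % n_folds
    return folds


def make_cv_plan(
    dyad_ids: list[str],
    dyad_labels: np.ndarray,
    n_outer_folds: int = 7,
    n_outer_perms: int = 10,
    n_inner_folds: int = 10,
    n_inner_perms: int = 1,
    seed: int = 0,
) -> CvPlan:
    """Build the repeated, stratified, dyad-integral outer CV assignment.

    Every outer fold receives at least one dyad of each class; a class with
    fewer dyads than outer folds makes stratification infeasible.
    """
    labels = np.asarray(dyad_labels)
    if len(dyad_ids) != labels.size:
        raise ConfigError("dyad_ids and dyad_labels must be matched")
    if n_inner_perms != 1:
        raise ConfigError("the inner loop uses exactly one permutation")
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValidationError("stratification infeasible: a single class is present")
    if counts.min() < n_outer_folds:
        small = classes[int(np.argmin(counts))]
        raise ValidationError(
            f"stratification infeasible: class {small!r} has {counts.min()} dyads, "
            f"fewer than {n_outer_folds} outer folds"
        )
    rng = np.random.default_rng(seed)
    assignments = np.stack(
        [_stratified_folds(labels, n_outer_folds, rng) for _ in range(n_outer_perms)]
    )
    return CvPlan(
        dyad_ids=list(dyad_ids),
        outer_assignments=assignments,
        n_outer_folds=n_outer_folds,
        n_inner_folds=n_inner_folds,
        inner_seed=int(rng.integers(2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# nested fit/predict


@dataclass
class ClassifierReport:
    participant_ids: list[str]
    true_labels: np.ndarray
    decision_scores: np.ndarray  # mean over outer permutations, threshold-shifted
    predicted_labels: np.ndarray  # majority vote over outer permutations
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    permutation_p: float = field(default=float("nan"))


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """Arithmetic mean of sensitivity and specificity."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return (sensitivity + specificity) / 2.0


def _preprocess_fit(X_train: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Zero-variance pruning + [-1, 1] scaling bounds from training rows only."""
    lo = X_train.min(axis=0)
    hi = X_train.max(axis=0)
    keep = hi > lo
    if not keep.any():
        raise ValidationError("all features have zero variance in the training partition")
    return keep, lo[keep], hi[keep]


def _preprocess_apply(X: np.ndarray, keep: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return -1.0 + 2.0 * (X[:, keep] - lo) / (hi - lo)


def _fit_svm(X: np.ndarray, y: np.ndarray, c: float) -> LinearSVC:
    clf = LinearSVC(
        C=c,
        penalty="l2",
        loss="squared_hinge",
        class_weight="balanced",
        tol=1e-6,
        max_iter=20000,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    return clf

def _bac_from_scores(y: np.ndarray, scores: np.ndarray) -> float:
    pred = (scores > 0).astype(int)
    pos = y == 1
    sens = float(np.mean(pred[pos] == 1)) if pos.any() else 0.0
    spec = float(np.mean(pred[~pos] == 0)) if (~pos).any() else 0.0
    return (sens + spec) / 2.0


def _youden_threshold(y: np.ndarray, scores: np.ndarray) -> float:
    """ROC-optimal (Youden J) operating point on inner out-of-fold scores."""
    if len(np.unique(y)) < 2:
        return 0.0
    fpr, tpr, thresholds = roc_curve(y, scores)
    j = tpr - fpr
    k = int(np.argmax(j))
    thr = thresholds[k]
    if not math.isfinite(thr):  # roc_curve prepends +inf
        finite = np.isfinite(thresholds)
        if not finite.any():
            return 0.0
        k = int(np.argmax(j[finite]))
        thr = thresholds[finite][k]
    return float(thr)


def fit_predict_nested(
    fm: FeatureMatrix,
    plan: CvPlan,
    grid: tuple[float, ...] = DEFAULT_C_GRID,
) -> ClassifierReport:
    """Run the nested, dyad-aware CV and report out-of-sample performance.

    Within each outer training partition: scaling bounds and zero-variance
    pruning are computed on training rows only; the inner loop picks the
    penalty C maximizing inner out-of-fold balanced accuracy; the decision
    threshold is shifted to the Youden-J optimum of the inner out-of-fold
    ROC; the refit model then scores the untouched outer test rows.
    Per-individual scores are averaged and labels majority-voted across
    outer permutations.
    """
    if plan.dyad_ids != fm.dyads:
        raise ConfigError("CV plan and feature matrix disagree on dyads")
    X, y = fm.X, fm.y
    dyad_pos = {d: k for k, d in enumerate(plan.dyad_ids)}
    row_dyad = np.asarray([dyad_pos[d] for d in fm.dyad_ids])
    n = X.shape[0]
    n_perms = plan.n_outer_perms
    scores = np.full((n_perms, n), np.nan)
    votes = np.zeros((n_perms, n), dtype=int)
    seed_seq = np.random.SeedSequence(plan.inner_seed)
    inner_seeds = seed_seq.generate_state(n_perms * plan.n_outer_folds).reshape(
        n_perms, plan.n_outer_folds
    )
    all_dyad_labels = fm.dyad_labels()
    for p in range(n_perms):
        fold_of_dyad = plan.outer_assignments[p]
        for f in range(plan.n_outer_folds):
            test_rows = fold_of_dyad[row_dyad] == f
            train_rows = ~test_rows
            Xtr_raw, ytr = X[train_rows], y[train_rows]
            keep, lo, hi = _preprocess_fit(Xtr_raw)
            Xtr = _preprocess_apply(Xtr_raw, keep, lo, hi)
            # inner dyad-stratified folds inside the outer training partition
            train_dyads = np.flatnonzero(
                np.bincount(row_dyad[train_rows], minlength=len(plan.dyad_ids)) > 0
            )
            inner_rng = np.random.default_rng(int(inner_seeds[p, f]))
            dyad_lab = all_dyad_labels[train_dyads]
            k_inner = min(plan.n_inner_folds, train_dyads.size)
            inner_folds = _stratified_folds(dyad_lab, k_inner, inner_rng)
            inner_fold_of_row = np.full(n, -1)
            for j, d in enumerate(train_dyads):
                inner_fold_of_row[row_dyad == d] = inner_folds[j]
            ifr = inner_fold_of_row[train_rows]
            oof = {c: np.full(ytr.size, np.nan) for c in grid}
            for g in range(k_inner):
                val = ifr == g
                fit = ~val
                if len(np.unique(ytr[fit])) < 2 or not val.any():
                    continue
                for c in grid:
                    clf = _fit_svm(Xtr[fit], ytr[fit], c)
                    oof[c][val] = clf.decision_function(Xtr[val])
            usable = np.isfinite(oof[grid[0]])
            if usable.any():
                bacs = [(c, _bac_from_scores(ytr[usable], oof[c][usable])) for c in grid]
                best_c = max(bacs, key=lambda kv: (kv[1], -kv[0]))[0]
                threshold = _youden_threshold(ytr[usable], oof[best_c][usable])
            else:
                best_c, threshold = grid[len(grid) // 2], 0.0
            clf = _fit_svm(Xtr, ytr, best_c)
            Xte = _preprocess_apply(X[test_rows], keep, lo, hi)
            s = clf.decision_function(Xte) - threshold
            scores[p, test_rows] = s
            votes[p, test_rows] = (s > 0).astype(int)
    mean_scores = scores.mean(axis=0)
    vote_share = votes.mean(axis=0)
    pred = np.where(
        vote_share == 0.5, (mean_scores > 0).astype(int), (vote_share > 0.5).astype(int)
    )
    pos = y == 1
    sens = float(np.mean(pred[pos] == 1)) if pos.any() else float("nan")
    spec = float(np.mean(pred[~pos] == 0)) if (~pos).any() else float("nan")
    auc = float(roc_auc_score(y, mean_scores)) if pos.any() and (~pos).any() else float("nan")
    return ClassifierReport(
        participant_ids=list(fm.participant_ids),
        true_labels=y.copy(),
        decision_scores=mean_scores,
        predicted_labels=pred,
        balanced_accuracy=balanced_accuracy(sens, spec),
        sensitivity=sens,
        specificity=spec,
        auc=auc,
    )


def label_permutation_test(
    fm: FeatureMatrix,
    plan: CvPlan,
    n_perm: int = 5000,
    seed: int = 0,
    grid: tuple[float, ...] = DEFAULT_C_GRID,
) -> tuple[float, float, np.ndarray]:
    """Dyad-level label-permutation test of the nested-CV balanced accuracy.

    Both members of a dyad are relabelled together; the CV fold structure
    is kept intact; the full nested pipeline is re-run per permutation.
    Returns ``(p_value, observed_bac, permuted_bacs)`` with
    ``p = (1 + #{perm >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    observed = fit_predict_nested(fm, plan, grid).balanced_accuracy
    rng = np.random.default_rng(seed)
    dyad_lab = fm.dyad_labels()
    dyads = fm.dyads
    perm_bacs = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = rng.permutation(dyad_lab)
        lab_of = dict(zip(dyads, shuffled))
        y_perm = np.asarray([lab_of[d] for d in fm.dyad_ids])
        fm_perm = FeatureMatrix(
            X=fm.X,
            y=y_perm,
            feature_names=fm.feature_names,
            participant_ids=fm.participant_ids,
            dyad_ids=fm.dyad_ids,
        )
        perm_bacs[i] = fit_predict_nested(fm_perm, plan, grid).balanced_accuracy
    p = (1.0 + float(np.sum(perm_bacs >= observed))) / (1.0 + n_perm)
    return p, observed, perm_bacs
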