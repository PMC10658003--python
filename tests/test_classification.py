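import numpy as np
import pandas as pd
import pytest

from convosync.classification import (
    FeatureMatrix,
    balanced_accuracy,
    build_feature_matrix,
    fit_predict_nested,
    label_permutation_test,
    make_cv_plan,
)
from convosync.errors import ConfigError, ValidationError
from convosync.io_formats import FEATURE_COLUMNS, TASKS


def gaussian_fm(n_dyads=14, n_pos=7, n_features=10, effect=0.0, seed=0):
    """Direct feature matrix: dyad members share the class mean shift."""
    rng = np.random.default_rng(seed)
    rows, y, dyads, pids = [], [], [], []
    for k in range(n_dyads):
        pos = k < n_pos
        for m in range(2):
            rows.append(rng.normal(effect if pos else 0.0, 1.0, n_features))
            y.append(int(pos))
            dyads.append(f"d{k:03d}")
            pids.append(f"d{k:03d}_p{m}")
    return FeatureMatrix(
        X=np.asarray(rows), y=np.asarray(y),
        feature_names=[f"f{i}" for i in range(n_features)],
        participant_ids=pids, dyad_ids=dyads,
    )


def synthetic_feature_table(n_dyads=4, shift_by_task=False):
    rng = np.random.default_rng(1)
    rows = []
    for k in range(n_dyads):
        for m in range(2):
            for ti, task in enumerate(TASKS):
                vals = {c: float(rng.normal(10 * ti if shift_by_task else 0.0, 1.0))
                        for c in FEATURE_COLUMNS}
                rows.append(dict(participant_id=f"d{k}_p{m}", dyad_id=f"d{k}",
                                 conversation_id=f"d{k}_{task}", task=task, **vals))
    return pd.DataFrame(rows)


def test_balanced_accuracy_identity_and_bounds():
    assert balanced_accuracy(0.738, 0.786) == pytest.approx(0.762)
    assert balanced_accuracy(1.0, 1.0) == 1.0
    assert balanced_accuracy(0.0, 1.0) == 0.5
    with pytest.raises(ValueError):
        balanced_accuracy(1.2, 0.5)


def test_feature_matrix_shape_and_exclusion():
    table = synthetic_feature_table(n_dyads=4)
    types = {f"d{k}": "mixed" if k < 2 else "non_autistic" for k in range(4)}
    fm = build_feature_matrix(table, types)
    assert fm.X.shape == (8, 2 * len(FEATURE_COLUMNS))
    assert fm.y.sum() == 4
    # dropping one individual's meal_planning rows excludes that individual
    short = table[~((table["participant_id"] == "d0_p0") & (table["task"] == "meal_planning"))]
    fm2 = build_feature_matrix(short, types)
    assert fm2.X.shape[0] == 7
    assert "d0_p0" not in fm2.participant_ids


def test_task_blocks_are_ordered_not_mixed():
    table = synthetic_feature_table(shift_by_task=True)
    types = {f"d{k}": "mixed" for k in range(4)}
    types.update({"d2": "non_autistic", "d3": "non_autistic"})
    fm = build_feature_matrix(table, types)
    n = len(FEATURE_COLUMNS)
    assert all(name.endswith("__hobbies") for name in fm.feature_names[:n])
    assert all(name.endswith("__meal_planning") for name in fm.feature_names[n:])
    assert fm.X[:, :n].mean() == pytest.approx(0.0, abs=0.5)
    assert fm.X[:, n:].mean() == pytest.approx(10.0, abs=0.5)


def test_cv_plan_fold_sizes_and_stratification():
    dyads = [f"d{k}" for k in range(40)]
    labels = np.array([1] * 26 + [0] * 14)
    plan = make_cv_plan(dyads, labels, seed=3)
    assert plan.outer_assignments.shape == (10, 40)
    for p in range(10):
        folds = plan.outer_assignments[p]
        sizes = sorted(np.bincount(folds, minlength=7))
        assert sizes == [5, 5, 6, 6, 6, 6, 6]
        mixed_per_fold = [np.sum(labels[folds == f]) for f in range(7)]
        assert set(mixed_per_fold) <= {3, 4}
        na_per_fold = [np.sum(labels[folds == f] == 0) for f in range(7)]
        assert set(na_per_fold) == {2}
    # determinism
    again = make_cv_plan(dyads, labels, seed=3)
    assert np.array_equal(plan.outer_assignments, again.outer_assignments)
    assert plan.inner_seed == again.inner_seed


def test_cv_plan_infeasible_stratification_errors():
    with pytest.raises(ValidationError):
        make_cv_plan([f"d{k}" for k in range(10)], np.array([1] * 6 + [0] * 4))
    with pytest.raises(ValidationError):
        make_cv_plan([f"d{k}" for k in range(10)], np.ones(10, dtype=int))


def test_dyad_integrity_in_every_fold_of_every_permutation():
    fm = gaussian_fm(n_dyads=16, n_pos=9, effect=1.0, seed=2)
    plan = make_cv_plan(fm.dyads, fm.dyad_labels(), seed=5)
    dyad_pos = {d: k for k, d in enumerate(plan.dyad_ids)}
    for p in range(plan.n_outer_perms):
        folds = plan.outer_assignments[p]
        row_folds = np.asarray([folds[dyad_pos[d]] for d in fm.dyad_ids])
        for k in range(0, len(row_folds), 2):
            assert row_folds[k] == row_folds[k + 1]


def test_separable_dyads_classified_correctly():
    fm = gaussian_fm(n_dyads=14, n_pos=7, effect=3.0, seed=4)
    plan = make_cv_plan(fm.dyads, fm.dyad_labels(), n_outer_perms=2, n_inner_folds=3, seed=6)
    rep = fit_predict_nested(fm, plan, grid=(0.25, 1.0, 4.0))
    assert rep.balanced_accuracy >= 0.9
    assert rep.balanced_accuracy == pytest.approx((rep.sensitivity + rep.specificity) / 2)
    assert rep.auc > 0.95


def test_no_leakage_from_test_rows():
    """Perturbing one test row leaves scores of its fold mates unchanged."""
    fm = gaussian_fm(n_dyads=14, n_pos=7, effect=1.0, seed=8)
    plan = make_cv_plan(fm.dyads, fm.dyad_labels(), n_outer_perms=1, n_inner_folds=3, seed=9)
    rep = fit_predict_nested(fm, plan, grid=(1.0,))
    folds = plan.outer_assignments[0]
    dyad_pos = {d: k for k, d in enumerate(plan.dyad_ids)}
    row_folds = np.asarray([folds[dyad_pos[d]] for d in fm.dyad_ids])
    target_fold = row_folds[0]
    fm2 = gaussian_fm(n_dyads=14, n_pos=7, effect=1.0, seed=8)
    fm2.X[0] += 1e4  # wild perturbation of one *test* row of that fold
    rep2 = fit_predict_nested(fm2, plan, grid=(1.0,))
    mates = (row_folds == target_fold) & (np.arange(len(row_folds)) != 0)
    assert np.allclose(rep.decision_scores[mates], rep2.decision_scores[mates])


def test_permutation_p_value_bounds_and_strong_signal():
    fm = gaussian_fm(n_dyads=14, n_pos=8, effect=3.0, seed=10)
    plan = make_cv_plan(fm.dyads, fm.dyad_labels(), n_outer_folds=3, n_outer_perms=1,
                        n_inner_folds=2, seed=11)
    p, observed, perm_bacs = label_permutation_test(fm, plan, n_perm=200, seed=12, grid=(1.0,))
    assert p >= 1.0 / 201.0
    assert observed >= 0.9
    assert p <= 0.01
    with pytest.raises(ConfigError):
        label_permutation_test(fm, plan, n_perm=0)


def test_all_zero_variance_features_error():
    fm = gaussian_fm(n_dyads=14, n_pos=7, effect=0.0, seed=13)
    fm.X[:] = 1.0
    plan = make_cv_plan(fm.dyads, fm.dyad_labels(), n_outer_perms=1, seed=14)
    with pytest.raises(ValidationError):
        fit_predict_nested(fm, plan, grid=(1.0,))
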