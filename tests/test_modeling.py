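"""Tests of aggregation, penalised solvers, CV machinery and metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from sklearn.linear_model import LinearRegression, LogisticRegression

from wearra import modeling as md


def _matrix_index(pids, periods):
    return pd.MultiIndex.from_arrays([pids, periods],
                                     names=["participant_id", "period_id"])


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def _daily_frame():
    rows = []
    for pid in ("a", "b"):
        for d in range(14):
            rows.append({"participant_id": pid, "day_index": d,
                         "f1": float(d), "f2": 1.0})
    return pd.DataFrame(rows)


def test_aggregate_fortnightly_mean():
    df = pd.DataFrame({"participant_id": ["a"] * 3, "day_index": [0, 1, 2],
                       "f": [1.0, 2.0, 3.0]})
    fm = md.aggregate_features(df, "fortnightly", {"f": "TVDA"})
    assert fm.X.loc[("a", 0), "f"] == pytest.approx(2.0)


def test_aggregate_weekly_rows():
    fm = md.aggregate_features(_daily_frame(), "weekly", {"f1": "A", "f2": "B"})
    assert len(fm.X) == 4  # 2 participants x 2 weeks
    assert fm.X.loc[("a", 0), "f1"] == pytest.approx(3.0)
    assert fm.X.loc[("a", 1), "f1"] == pytest.approx(10.0)


def test_aggregate_skips_missing_days():
    df = pd.DataFrame({"participant_id": ["a"] * 3, "day_index": [0, 1, 2],
                       "f": [1.0, np.nan, 3.0]})
    fm = md.aggregate_features(df, "fortnightly", {"f": "X"})
    assert fm.X.loc[("a", 0), "f"] == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# proximal operator
# ---------------------------------------------------------------------------

def test_prox_group_shrinkage_boundary():
    groups = [np.array([0, 1])]
    out = md.prox_sparse_group(np.array([3.0, 4.0]), 0.0, 5.0 / np.sqrt(2), groups)
    assert np.allclose(out, 0.0)


def test_prox_group_partial_shrinkage():
    groups = [np.array([0, 1])]
    out = md.prox_sparse_group(np.array([3.0, 4.0]), 0.0, 2.5 / np.sqrt(2), groups)
    assert np.allclose(out, [1.5, 2.0])


def test_prox_soft_threshold_only():
    groups = [np.array([0, 1])]
    out = md.prox_sparse_group(np.array([3.0, -0.5]), 1.0, 0.0, groups)
    assert np.allclose(out, [2.0, 0.0])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(hst.integers(min_value=0, max_value=10_000))
def test_prox_is_nonexpansive(seed):
    rng = np.random.default_rng(seed)
    p = 6
    groups = [np.array([0, 1, 2]), np.array([3, 4, 5])]
    v1, v2 = rng.normal(0, 2, p), rng.normal(0, 2, p)
    t1, tg = rng.uniform(0, 1), rng.uniform(0, 1)
    d_out = np.linalg.norm(md.prox_sparse_group(v1, t1, tg, groups) -
                           md.prox_sparse_group(v2, t1, tg, groups))
    assert d_out <= np.linalg.norm(v1 - v2) + 1e-9


# ---------------------------------------------------------------------------
# penalised solver oracles
# ---------------------------------------------------------------------------

def test_ridge_matches_closed_form(rng):
    n, p, lam = 30, 5, 0.7
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0)
    y = rng.standard_normal(n)
    pen = md.PenaltySpec("ridge", lam)
    m = md.fit_penalised(X, y, pen, task="regression", rel_tol=1e-14)
    # intercept = mean(y) at the optimum for centred X; beta solves
    # (X'X/n + lam I) beta = X'(y - ybar)/n
    yc = y - y.mean()
    closed = np.linalg.solve(X.T @ X / n + lam * np.eye(p), X.T @ yc / n)
    assert np.allclose(m.coef, closed, atol=1e-6)
    assert m.intercept == pytest.approx(y.mean(), abs=1e-6)


def test_lambda_zero_matches_ols(rng):
    n, p = 40, 4
    X = rng.standard_normal((n, p))
    y = X @ np.array([1.0, -2.0, 0.5, 0.0]) + rng.normal(0, 0.1, n)
    m = md.fit_penalised(X, y, md.PenaltySpec("lasso", 0.0), task="regression",
                         rel_tol=1e-14)
    ref = LinearRegression().fit(X, y)
    assert np.allclose(m.coef, ref.coef_, atol=1e-4)
    assert m.intercept == pytest.approx(ref.intercept_, abs=1e-4)


def test_lambda_zero_matches_unpenalised_logistic(rng):
    n, p = 200, 3
    X = rng.standard_normal((n, p))
    y = (rng.random(n) < 1 / (1 + np.exp(-(X @ [1.0, -1.0, 0.5])))).astype(float)
    m = md.fit_penalised(X, y, md.PenaltySpec("lasso", 0.0), rel_tol=1e-14)
    ref = LogisticRegression(C=np.inf, max_iter=5000, tol=1e-12).fit(X, y)
    assert np.allclose(m.coef, ref.coef_.ravel(), atol=1e-4)


def test_sgl_alpha_one_equals_lasso(rng):
    n, p = 50, 8
    X = rng.standard_normal((n, p))
    y = X @ np.concatenate([np.ones(3), np.zeros(5)]) + rng.normal(0, 0.3, n)
    groups = {"g0": [0, 1, 2, 3], "g1": [4, 5, 6, 7]}
    sgl = md.fit_penalised(X, y, md.PenaltySpec("sparse_group_lasso", 0.1, 1.0),
                           task="regression", groups=groups, rel_tol=1e-14)
    lasso = md.fit_penalised(X, y, md.PenaltySpec("lasso", 0.1),
                             task="regression", rel_tol=1e-14)
    assert np.allclose(sgl.coef, lasso.coef, atol=1e-6)


@pytest.mark.parametrize("family, alpha, task", [
    ("lasso", 1.0, "regression"), ("ridge", 0.0, "regression"),
    ("elastic_net", 0.5, "regression"), ("sparse_group_lasso", 0.5, "regression"),
    ("elastic_net", 0.5, "classification"),
    ("sparse_group_lasso", 0.5, "classification"),
])
def test_kkt_conditions_at_convergence(rng, family, alpha, task):
    n, p = 80, 12
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0)
    beta = np.concatenate([[1.5, -1.0, 0.8], np.zeros(p - 3)])
    eta = X @ beta
    y = eta + rng.normal(0, 0.5, n) if task == "regression" else \
        (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    groups = {f"g{k}": list(range(3 * k, 3 * k + 3)) for k in range(4)}
    pen = md.PenaltySpec(family, 0.08, alpha)
    m = md.fit_penalised(X, y, pen, task=task,
                         groups=groups if family == "sparse_group_lasso" else None,
                         rel_tol=1e-13)
    res = md.kkt_residual(m, X, y,
                          groups if family == "sparse_group_lasso" else None)
    assert res <= 1e-6


def test_objective_history_nonincreasing(rng):
    X = rng.standard_normal((60, 10))
    y = rng.standard_normal(60)
    m = md.fit_penalised(X, y, md.PenaltySpec("elastic_net", 0.05, 0.5),
                         task="regression")
    assert (np.diff(m.objective_history) <= 1e-12).all()
    assert m.converged


def test_solution_path_sparsity_monotone(rng):
    """Nonzero-coefficient count is nonincreasing in lambda (<=1 inversion)."""
    n, p = 60, 15
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0)
    y = X @ np.concatenate([np.ones(4), np.zeros(p - 4)]) + rng.normal(0, 0.5, n)
    grid = md.lambda_grid(X, y, md.PenaltySpec("lasso", 1.0), "regression", 15)
    counts = []
    beta, b = None, 0.0
    for lam in grid:  # descending lambda -> nondecreasing support
        m = md.fit_penalised(X, y, md.PenaltySpec("lasso", float(lam)),
                             task="regression", beta0=beta, b0=b)
        beta, b = m.coef, m.intercept
        counts.append(int((m.coef != 0).sum()))
    inversions = int(np.sum(np.diff(counts) < 0))
    assert inversions <= 1


def test_nonconvergence_flagged_not_raised(rng):
    X = rng.standard_normal((30, 5))
    y = rng.standard_normal(30)
    with pytest.warns(UserWarning):
        m = md.fit_penalised(X, y, md.PenaltySpec("lasso", 0.001),
                             task="regression", max_iter=3, rel_tol=1e-16)
    assert not m.converged
    assert np.isfinite(m.coef).all()


# ---------------------------------------------------------------------------
# folds, voting, metrics
# ---------------------------------------------------------------------------

def test_stratified_folds_exact_proportions():
    pids = np.array([f"p{i}" for i in range(60)])
    labels = np.repeat([0, 1], 30)
    folds = md.stratified_subject_kfold(pids, labels, 5, seed=0)
    for fold in folds:
        lab = labels[np.isin(pids, fold)]
        assert (lab == 0).sum() == 6 and (lab == 1).sum() == 6


def test_stratified_folds_remainders_within_one():
    pids = np.array([f"p{i}" for i in range(28)])
    labels = np.repeat([0, 1], [13, 15])
    folds = md.stratified_subject_kfold(pids, labels, 5, seed=1)
    sizes0 = sorted((labels[np.isin(pids, f)] == 0).sum() for f in folds)
    sizes1 = sorted((labels[np.isin(pids, f)] == 1).sum() for f in folds)
    assert max(sizes0) - min(sizes0) <= 1
    assert max(sizes1) - min(sizes1) <= 1
    assert sum(len(f) for f in folds) == 28


def test_stratified_folds_deterministic():
    pids = np.array([f"p{i}" for i in range(20)])
    labels = np.tile([0, 1], 10)
    a = md.stratified_subject_kfold(pids, labels, 4, seed=3)
    b = md.stratified_subject_kfold(pids, labels, 4, seed=3)
    assert all(np.array_equal(x, y) for x, y in zip(a, b))


def test_stratified_folds_k_too_large():
    with pytest.raises(ValueError):
        md.stratified_subject_kfold(np.array(["a", "b"]), np.array([0, 1]), 3, 0)


def test_majority_vote_rules():
    assert md.majority_vote(np.array([1, 1, 0])) == 1
    assert md.majority_vote(np.array([1, 0]), np.array([0.8, 0.6])) == 1
    assert md.majority_vote(np.array([1, 0]), np.array([0.2, 0.3])) == 0
    assert md.majority_vote(np.array([0])) == 0


def test_classification_metric_examples():
    out = md.classification_metrics([0, 1, 0, 1], [0, 1, 0, 1],
                                    [0.1, 0.2, 0.3, 0.4])
    assert out["auroc"] == pytest.approx(0.75)
    assert out["kappa"] == pytest.approx(1.0)
    assert out["macro_f1"] == pytest.approx(1.0)
    out = md.classification_metrics([1, 1, 0, 0], [1, 0, 1, 0])
    assert out["kappa"] == pytest.approx(0.0)


def test_single_class_auroc_undefined():
    out = md.classification_metrics([1, 1, 1], [1, 1, 0], [0.9, 0.8, 0.4])
    assert out["auroc"] is None


def test_regression_metric_examples(rng):
    y = rng.normal(0, 2, 25)
    out = md.regression_metrics(y, y)
    assert out["r2"] == pytest.approx(1.0) and out["mae"] == 0.0
    out = md.regression_metrics(y, y + 1.0)
    assert out["mae"] == pytest.approx(1.0) and out["rmse"] == pytest.approx(1.0)
    out = md.regression_metrics(y, np.full_like(y, y.mean()))
    assert out["r2"] == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# cross-validation hygiene
# ---------------------------------------------------------------------------

def _toy_matrix(rng, n_subj=24, n_periods=2, p=5, signal=2.0):
    pids = np.repeat([f"p{i}" for i in range(n_subj)], n_periods)
    periods = np.tile(np.arange(n_periods), n_subj)
    labels = pd.Series(np.repeat(np.tile([0, 1], n_subj // 2), 1),
                       index=[f"p{i}" for i in range(n_subj)])
    X = rng.standard_normal((n_subj * n_periods, p))
    X[:, 0] += signal * labels.loc[pids].to_numpy()
    Xdf = pd.DataFrame(X, columns=[f"f{j}" for j in range(p)],
                       index=_matrix_index(pids, periods))
    fm = md.FeatureMatrix(Xdf, "weekly", {f"f{j}": "D" for j in range(p)})
    return fm, labels


def test_run_cv_partitions_participants(rng):
    fm, labels = _toy_matrix(rng)
    rep = md.run_cv(fm, labels, md.PenaltySpec("elastic_net", alpha_mix=0.5),
                    k=4, seed=0, n_lambda=6)
    fold_sets = {}
    for pid, fold in rep.fold_of.items():
        fold_sets.setdefault(fold, set()).add(pid)
    all_pids = set().union(*fold_sets.values())
    assert all_pids == set(labels.index)
    assert sum(len(s) for s in fold_sets.values()) == len(all_pids)
    obs_folds = rep.observations.groupby("participant_id")["fold"].nunique()
    assert (obs_folds == 1).all()


def test_run_cv_train_only_statistics(rng):
    """Poisoning the test fold's rows leaves the fitted preprocessing
    unchanged (statistics learned from training folds only)."""
    fm, labels = _toy_matrix(rng)
    rep = md.run_cv(fm, labels, md.PenaltySpec("elastic_net", alpha_mix=0.5),
                    k=4, seed=0, n_lambda=6)
    test_pids_f0 = [pid for pid, f in rep.fold_of.items() if f == 0]
    poisoned = fm.X.copy()
    rows = poisoned.index.get_level_values("participant_id").isin(test_pids_f0)
    poisoned.loc[rows, :] = 1e6
    rep2 = md.run_cv(md.FeatureMatrix(poisoned, fm.aggregation, fm.domains),
                     labels, md.PenaltySpec("elastic_net", alpha_mix=0.5),
                     k=4, seed=0, n_lambda=6)
    m1 = [m for m in rep.models][0]
    m2 = [m for m in rep2.models][0]
    assert np.allclose(m1.standardise_mean, m2.standardise_mean)
    assert np.allclose(m1.impute_medians, m2.impute_medians)
    assert np.allclose(m1.coef, m2.coef)


def test_run_cv_deterministic(rng):
    fm, labels = _toy_matrix(rng)
    pen = md.PenaltySpec("lasso")
    r1 = md.run_cv(fm, labels, pen, k=4, seed=5, n_lambda=6)
    r2 = md.run_cv(fm, labels, pen, k=4, seed=5, n_lambda=6)
    assert r1.subject_metrics == r2.subject_metrics
    assert r1.chosen_lambdas == r2.chosen_lambdas
    pd.testing.assert_frame_equal(r1.observations, r2.observations)


def test_run_cv_regression_task(rng):
    n_subj = 20
    pids = [f"p{i}" for i in range(n_subj)]
    y = pd.Series(rng.normal(0, 2, n_subj), index=pids)
    X = rng.standard_normal((n_subj, 4))
    X[:, 0] = y.to_numpy() + rng.normal(0, 0.1, n_subj)
    Xdf = pd.DataFrame(X, columns=list("abcd"),
                       index=_matrix_index(pids, [0] * n_subj))
    fm = md.FeatureMatrix(Xdf, "fortnightly", {c: "D" for c in "abcd"})
    rep = md.run_cv(fm, y, md.PenaltySpec("elastic_net", alpha_mix=0.5),
                    task="regression", k=4, seed=0, n_lambda=8)
    assert rep.subject_metrics["r2"] > 0.9


def test_pro_only_model_identifies_ra(study_features, study_cfg):
    """PRO-only elastic net separates RA from HC (HC PROs are near-degenerate
    at healthy values), subject-wise F1 >= 0.9."""
    from wearra import experiments as ex

    labels = ex._labels(study_features.cohort, "ra_vs_hc")
    matrix = study_features.matrix(("PRO",), "fortnightly")
    rep = md.run_cv(matrix, labels, md.PenaltySpec("elastic_net", alpha_mix=0.5),
                    k=5, seed=0)
    assert rep.subject_metrics["macro_f1"] >= 0.9
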