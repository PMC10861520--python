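"""Penalised linear modelling of RA status and severity.

The model family is the regularised (logistic/linear) regression suite used
for wearable-outcome studies: lasso, ridge, elastic net, and the sparse-group
lasso (SG-lasso) with feature-domain groups, which selects a sparse set of
domains and a sparse set of features within each selected domain.

The SG-lasso objective for coefficients beta (intercept unpenalised) is

    (1/n) * loss(y, X beta + b)
      + lambda * [ alpha * ||beta||_1 + (1 - alpha) * sum_g sqrt(p_g) ||beta_g||_2 ]

with logistic deviance or half squared error as the loss.  It is solved by
monotone FISTA with the composed proximal operator (elementwise
soft-threshold, then groupwise shrinkage).  Elastic net uses the same solver
with the ridge part folded into the smooth term.

Evaluation follows the subject-wise protocol: stratified participant-level
k-fold cross-validation (no participant spans train and test), per-fold
standardisation and median imputation from training data only, inner CV for
lambda, and subject-level predictions by majority vote over a participant's
observation-level predictions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score, f1_score, roc_auc_score

log = logging.getLogger(__name__)

MAX_ITER = 10_000
REL_TOL = 1e-8


@dataclass
class PenaltySpec:
    family: str  # lasso | ridge | elastic_net | sparse_group_lasso
    lam: float = 0.1
    alpha_mix: float = 0.5  # l1 share (elastic net / SG-lasso); forced for lasso/ridge

    def __post_init__(self):
        if self.family not in ("lasso", "ridge", "elastic_net", "sparse_group_lasso"):
            raise ValueError(f"unknown penalty family {self.family!r}")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")
        if self.family == "lasso":
            self.alpha_mix = 1.0
        elif self.family == "ridge":
            self.alpha_mix = 0.0
        if not 0.0 <= self.alpha_mix <= 1.0:
            raise ValueError("alpha_mix must be in [0, 1]")


@dataclass
class FittedPenalisedModel:
    feature_names: list[str]
    coef: np.ndarray  # on the standardised scale
    intercept: float
    task: str  # classification | regression
    penalty: PenaltySpec
    n_iter: int
    converged: bool
    final_objective: float
    objective_history: np.ndarray = field(repr=False, default=None)
    # preprocessing learned on the training fold
    impute_medians: np.ndarray | None = None
    standardise_mean: np.ndarray | None = None
    standardise_sd: np.ndarray | None = None

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float).copy()
        if self.impute_medians is not None:
            nan = np.isnan(X)
            if nan.any():
                X[nan] = np.broadcast_to(self.impute_medians, X.shape)[nan]
        if self.standardise_mean is not None:
            X = (X - self.standardise_mean) / self.standardise_sd
        return X

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self._prepare(X) @ self.coef + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.task != "classification":
            raise ValueError("probabilities only defined for classification")
        return 1.0 / (1.0 + np.exp(-self.decision_function(X)))

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        if self.task == "classification":
            return (self.predict_proba(X) >= threshold).astype(int)
        return self.decision_function(X)


# ---------------------------------------------------------------------------
# proximal operator and solver
# ---------------------------------------------------------------------------

def prox_sparse_group(v: np.ndarray, t_l1: float, t_group: float,
                      groups: list[np.ndarray]) -> np.ndarray:
    """Composed SG-lasso prox: soft-threshold, then groupwise shrinkage.

    u = soft(v, t_l1); then per group g with weight sqrt(p_g):
    u_g <- u_g * max(0, 1 - t_group * sqrt(p_g) / ||u_g||_2).
    """
    if t_l1 < 0 or t_group < 0:
        raise ValueError("thresholds must be nonnegative")
    u = np.sign(v) * np.maximum(np.abs(v) - t_l1, 0.0)
    if t_group > 0:
        for idx in groups:
            norm = np.linalg.norm(u[idx])
            if norm == 0:
                continue
            u[idx] *= max(0.0, 1.0 - t_group * np.sqrt(idx.size) / norm)
    return u


def _loss_grad(Xb: np.ndarray, y: np.ndarray, task: str) -> tuple[float, np.ndarray]:
    """(mean loss, d loss / d eta) for eta = X beta + b."""
    n = y.size
    if task == "regression":
        r = Xb - y
        return 0.5 * float(r @ r) / n, r / n
    # logistic with y in {0,1}: mean log(1 + exp(-s*eta)), s = 2y-1
    s = 2.0 * y - 1.0
    z = -s * Xb
    # stable log1p(exp(z))
    loss = float(np.mean(np.logaddexp(0.0, z)))
    p = 1.0 / (1.0 + np.exp(-Xb))
    return loss, (p - y) / n


def _penalty_value(beta: np.ndarray, pen: PenaltySpec,
                   groups: list[np.ndarray]) -> float:
    lam, a = pen.lam, pen.alpha_mix
    if lam == 0:
        return 0.0
    l1 = float(np.abs(beta).sum())
    if pen.family == "sparse_group_lasso":
        gsum = sum(np.sqrt(idx.size) * np.linalg.norm(beta[idx]) for idx in groups)
        return lam * (a * l1 + (1 - a) * gsum)
    # elastic-net family (lasso/ridge are its ends)
    return lam * (a * l1 + 0.5 * (1 - a) * float(beta @ beta))


def fit_penalised(X: np.ndarray, y: np.ndarray, penalty: PenaltySpec,
                  task: str = "classification",
                  groups: dict[str, list[int]] | None = None,
                  beta0: np.ndarray | None = None, b0: float = 0.0,
                  max_iter: int = MAX_ITER, rel_tol: float = REL_TOL,
                  feature_names: list[str] | None = None,
                  lipschitz: float | None = None) -> FittedPenalisedModel:
    """Fit a penalised linear model by monotone FISTA.

    ``X`` is expected standardised; the intercept is unpenalised.  ``groups``
    maps group name -> column indices and is required for the SG-lasso.
    Convergence: relative objective change < ``rel_tol`` or ``max_iter``
    iterations (non-convergence is flagged, not raised).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if task not in ("classification", "regression"):
        raise ValueError(f"unknown task {task!r}")
    if penalty.family == "sparse_group_lasso":
        if not groups:
            raise ValueError("sparse_group_lasso requires a group map")
        gidx = [np.asarray(ix, dtype=int) for ix in groups.values()]
        covered = np.sort(np.concatenate(gidx))
        if not np.array_equal(covered, np.arange(p)):
            raise ValueError("groups must partition the feature columns")
    else:
        gidx = []

    lam, a = penalty.lam, penalty.alpha_mix
    smooth_ridge = lam * (1 - a) if penalty.family in ("ridge", "elastic_net") else 0.0
    t_l1 = lam * a if penalty.family != "ridge" else lam * a  # a=0 for ridge
    t_group = lam * (1 - a) if penalty.family == "sparse_group_lasso" else 0.0

    # Lipschitz constant of the smooth part (augmented with intercept column)
    if lipschitz is None:
        Xa = np.hstack([X, np.ones((n, 1))])
        lipschitz = np.linalg.norm(Xa, 2) ** 2 / n * \
            (0.25 if task == "classification" else 1.0)
    L = lipschitz + smooth_ridge
    step = 1.0 / max(L, 1e-12)

    beta = np.zeros(p) if beta0 is None else beta0.astype(float).copy()
    b = float(b0)
    is_classif = task == "classification"
    s_signed = 2.0 * y - 1.0  # labels in {-1, +1} for the logistic loss
    sgl = penalty.family == "sparse_group_lasso"
    st_l1, st_g = step * t_l1, step * t_group

    lam_a = lam * a
    lam_g = lam * (1 - a)

    def full_objective(beta_, b_):
        # ridge share of the elastic net sits in the smooth gradient but is
        # part of the reported penalised objective in the penalty term below
        eta = X @ beta_ + b_
        if is_classif:
            loss = float(np.logaddexp(0.0, -s_signed * eta).sum()) / n
        else:
            r = eta - y
            loss = 0.5 * float(r @ r) / n
        if lam == 0:
            return loss
        if sgl:
            gsum = sum(np.sqrt(idx.size) * np.linalg.norm(beta_[idx]) for idx in gidx)
            return loss + lam_a * float(np.abs(beta_).sum()) + lam_g * gsum
        return loss + lam_a * float(np.abs(beta_).sum()) \
            + 0.5 * lam_g * float(beta_ @ beta_)

    def prox_step(beta_, b_):
        eta = X @ beta_ + b_
        if is_classif:
            geta = (1.0 / (1.0 + np.exp(-eta)) - y) / n
        else:
            geta = (eta - y) / n
        gb = geta @ X
        if smooth_ridge:
            gb = gb + smooth_ridge * beta_
        v = beta_ - step * gb
        if sgl:
            nb = prox_sparse_group(v, st_l1, st_g, gidx)
        else:
            nb = np.sign(v) * np.maximum(np.abs(v) - st_l1, 0.0)
        return nb, b_ - step * float(geta.sum())

    obj = full_objective(beta, b)
    history = [obj]
    zbeta, zb = beta.copy(), b  # momentum point
    tk = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        cand_beta, cand_b = prox_step(zbeta, zb)
        cand_obj = full_objective(cand_beta, cand_b)
        if cand_obj > obj:  # monotone fallback: plain prox step from x_k
            cand_beta, cand_b = prox_step(beta, b)
            cand_obj = full_objective(cand_beta, cand_b)
            tk = 1.0  # restart momentum
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * tk * tk)) / 2.0
        zbeta = cand_beta + (tk - 1.0) / t_next * (cand_beta - beta)
        zb = cand_b + (tk - 1.0) / t_next * (cand_b - b)
        tk = t_next
        prev_obj, obj = obj, min(cand_obj, obj)
        beta, b = cand_beta, cand_b
        history.append(obj)
        if abs(prev_obj - obj) <= rel_tol * max(abs(prev_obj), 1e-12):
            converged = True
            break
    if not converged:
        warnings.warn(f"penalised fit did not converge in {max_iter} iterations")
    names = feature_names or [f"x{j}" for j in range(p)]
    return FittedPenalisedModel(names, beta, float(b), task, penalty,
                                it, converged, float(obj), np.asarray(history))


def kkt_residual(model: FittedPenalisedModel, X: np.ndarray, y: np.ndarray,
                 groups: dict[str, list[int]] | None = None) -> float:
    """Max violation of the first-order optimality conditions at the solution.

    Zero groups: dual-norm bound ||soft(g_g, lam*a)||_2 <= lam*(1-a)*sqrt(p_g);
    active coordinates: stationarity residual; zero coordinates in active
    groups: |g_j| <= lam*a (plus the group-gradient term).  Intercept: |g_b|.
    """
    beta, b = model.coef, model.intercept
    pen = model.penalty
    lam, a = pen.lam, pen.alpha_mix
    y = np.asarray(y, dtype=float)
    n = y.size
    _, geta = _loss_grad(X @ beta + b, y, model.task)
    g = geta @ X
    res = abs(float(geta.sum()))  # intercept stationarity
    if pen.family == "sparse_group_lasso":
        gidx = [np.asarray(ix, dtype=int) for ix in (groups or {}).values()]
        for idx in gidx:
            w = lam * (1 - a) * np.sqrt(idx.size)
            bg = beta[idx]
            gg = g[idx]
            if np.linalg.norm(bg) == 0:
                soft = np.sign(gg) * np.maximum(np.abs(gg) - lam * a, 0.0)
                res = max(res, max(0.0, float(np.linalg.norm(soft)) - w))
            else:
                u = bg / np.linalg.norm(bg)
                for jj, j in enumerate(idx):
                    if bg[jj] != 0:
                        r = gg[jj] + lam * a * np.sign(bg[jj]) + w * u[jj]
                        res = max(res, abs(float(r)))
                    else:
                        res = max(res, max(0.0, abs(float(gg[jj] + w * u[jj])) - lam * a))
    else:
        ridge = lam * (1 - a)
        for j in range(beta.size):
            gj = g[j] + ridge * beta[j]
            if beta[j] != 0:
                res = max(res, abs(float(gj + lam * a * np.sign(beta[j]))))
            else:
                res = max(res, max(0.0, abs(float(gj)) - lam * a))
    return res


def lambda_grid(X: np.ndarray, y: np.ndarray, penalty: PenaltySpec,
                task: str, n_points: int = 20, ratio: float = 1e-3) -> np.ndarray:
    """Descending log-spaced lambda grid from the smallest all-zero lambda.

    lambda_max is max_j |grad_j| at beta = 0 (intercept at its optimum),
    divided by the l1 share (floored at 0.01 so ridge gets a usable grid).
    """
    y = np.asarray(y, dtype=float)
    b0 = 0.0
    if task == "classification":
        pbar = np.clip(y.mean(), 1e-6, 1 - 1e-6)
        b0 = float(np.log(pbar / (1 - pbar)))
    else:
        b0 = float(y.mean())
    _, geta = _loss_grad(np.full(y.size, b0), y, task)
    gmax = float(np.max(np.abs(geta @ X)))
    a_eff = max(penalty.alpha_mix, 0.01)
    lam_max = gmax / a_eff
    return np.geomspace(lam_max, lam_max * ratio, n_points)


# ---------------------------------------------------------------------------
# feature aggregation
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Observations x features with domain groups and aggregation metadata."""

    X: pd.DataFrame  # index (participant_id, period_id)
    aggregation: str  # daily | weekly | fortnightly
    domains: dict[str, str]  # feature -> domain

    def participants(self) -> np.ndarray:
        return self.X.index.get_level_values("participant_id").unique().to_numpy()

    def group_indices(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for j, c in enumerate(self.X.columns):
            out.setdefault(self.domains.get(c, "OTHER"), []).append(j)
        return out


_PERIOD_DAYS = {"daily": 1, "weekly": 7, "fortnightly": 14}


def aggregate_features(daily: pd.DataFrame, level: str,
                       domains: dict[str, str]) -> FeatureMatrix:
    """Average daily feature rows into periods (mean over non-missing days).

    ``daily`` must carry participant_id and day_index columns; remaining
    columns are features.  Columns that end up all-missing are dropped.
    """
    if level not in _PERIOD_DAYS:
        raise ValueError(f"unknown aggregation level {level!r}")
    days = _PERIOD_DAYS[level]
    df = daily.copy()
    df["period_id"] = (df["day_index"] // days).astype(int)
    feats = [c for c in df.columns
             if c not in ("participant_id", "day_index", "period_id")]
    agg = df.groupby(["participant_id", "period_id"])[feats].mean()
    agg = agg.dropna(axis=1, how="all")
    dom = {c: domains[c] for c in agg.columns}
    return FeatureMatrix(agg, level, dom)


def combine_matrices(*mats: FeatureMatrix) -> FeatureMatrix:
    """Join feature matrices on (participant, period); aggregation must match."""
    levels = {m.aggregation for m in mats}
    if len(levels) != 1:
        raise ValueError("cannot combine matrices at different aggregations")
    X = pd.concat([m.X for m in mats], axis=1, join="outer")
    if X.columns.duplicated().any():
        raise ValueError("duplicate feature names across sources")
    dom: dict[str, str] = {}
    for m in mats:
        dom.update(m.domains)
    return FeatureMatrix(X, levels.pop(), dom)


# ---------------------------------------------------------------------------
# cross-validation machinery
# ---------------------------------------------------------------------------

def stratified_subject_kfold(participants: np.ndarray, labels: np.ndarray,
                             k: int, seed: int) -> list[np.ndarray]:
    """Participant-level stratified folds (per-fold class counts within 1).

    Returns a list of k arrays of participant ids (the test fold membership).
    """
    participants = np.asarray(participants)
    labels = np.asarray(labels)
    if k > participants.size:
        raise ValueError("k exceeds the number of participants")
    rng = np.random.default_rng(seed)
    folds: list[list] = [[] for _ in range(k)]
    slot = 0
    for lab in np.unique(labels):
        members = participants[labels == lab]
        members = members[rng.permutation(members.size)]
        for m in members:  # round-robin continues across classes
            folds[slot % k].append(m)
            slot += 1
    return [np.asarray(f) for f in folds]


def majority_vote(predictions: np.ndarray, scores: np.ndarray | None = None) -> int:
    """Modal class of a participant's observation-level predictions.

    Ties break toward the class with the higher mean positive-class score
    (or the positive class if no scores are given).
    """
    predictions = np.asarray(predictions, dtype=int)
    ones = int(predictions.sum())
    zeros = predictions.size - ones
    if ones != zeros:
        return int(ones > zeros)
    if scores is None:
        return 1
    return int(np.mean(scores) >= 0.5)


def classification_metrics(y: np.ndarray, yhat: np.ndarray,
                           scores: np.ndarray | None = None) -> dict[str, float | None]:
    """AUROC (rank statistic, ties half-counted), Cohen's kappa, macro-F1."""
    y = np.asarray(y, dtype=int)
    yhat = np.asarray(yhat, dtype=int)
    out: dict[str, float | None] = {}
    if scores is not None and np.unique(y).size == 2:
        out["auroc"] = float(roc_auc_score(y, scores))
    else:
        out["auroc"] = None
    out["kappa"] = float(cohen_kappa_score(y, yhat)) if np.unique(y).size > 1 else None
    out["macro_f1"] = float(f1_score(y, yhat, average="macro", zero_division=0))
    return out


def regression_metrics(y: np.ndarray, yhat: np.ndarray) -> dict[str, float | None]:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size != yhat.size:
        raise ValueError("length mismatch")
    resid = y - yhat
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    out = {
        "mae": float(np.mean(np.abs(resid))),
        "rmse": float(np.sqrt(np.mean(resid ** 2))),
        "r2": None if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot,
    }
    return out


@dataclass
class CvReport:
    fold_of: dict[str, int]
    observations: pd.DataFrame  # participant_id, period_id, fold, y, score, pred
    subjects: pd.DataFrame  # participant_id, y, pred (and score mean)
    observation_metrics: dict  # median + IQR across folds
    subject_metrics: dict
    chosen_lambdas: list[float]
    models: list[FittedPenalisedModel] = field(repr=False, default_factory=list)


def _preprocess_train(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    med = np.nanmedian(X, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    Xi = X.copy()
    nan = np.isnan(Xi)
    Xi[nan] = np.broadcast_to(med, Xi.shape)[nan]
    mean = Xi.mean(axis=0)
    sd = Xi.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (Xi - mean) / sd, med, mean, sd


def _validation_loss(model: FittedPenalisedModel, X: np.ndarray,
                     y: np.ndarray) -> float:
    eta = model.decision_function(X)
    loss, _ = _loss_grad(eta, y, model.task)
    return loss


def select_lambda(X: pd.DataFrame, y: pd.Series, penalty: PenaltySpec, task: str,
                  groups: dict[str, list[int]] | None, seed: int,
                  inner_k: int = 3, n_points: int = 20,
                  one_se: bool = False) -> float:
    """Inner subject-wise CV over a descending lambda path (warm-started).

    With ``one_se`` the largest lambda whose mean validation loss is within
    one standard error (across folds) of the minimum is returned instead of
    the CV minimiser — the usual choice when support recovery matters more
    than raw prediction.
    """
    pids = X.index.get_level_values("participant_id")
    upid = pids.unique().to_numpy()
    plab = np.asarray([y[pids == pid].iloc[0] for pid in upid])
    strat = plab if task == "classification" else np.zeros_like(plab, dtype=int)
    inner_k = min(inner_k, upid.size)
    folds = stratified_subject_kfold(upid, strat, inner_k, seed)
    Xs_all, _, _, _ = _preprocess_train(X.to_numpy(dtype=float))
    grid = lambda_grid(Xs_all, y.to_numpy(dtype=float), penalty, task, n_points)
    fold_losses = np.full((len(folds), grid.size), np.nan)
    names = list(X.columns)
    for f, test_pids in enumerate(folds):
        te = pids.isin(test_pids)
        Xtr_raw, ytr = X[~te].to_numpy(dtype=float), y[~te].to_numpy(dtype=float)
        Xte_raw, yte = X[te].to_numpy(dtype=float), y[te].to_numpy(dtype=float)
        if task == "classification" and np.unique(ytr).size < 2:
            continue
        Xtr, med, mean, sd = _preprocess_train(Xtr_raw)
        n = Xtr.shape[0]
        lip = np.linalg.norm(np.hstack([Xtr, np.ones((n, 1))]), 2) ** 2 / n \
            * (0.25 if task == "classification" else 1.0)
        beta, b = None, 0.0
        best, rises = np.inf, 0
        for i, lam in enumerate(grid):
            pen = PenaltySpec(penalty.family, float(lam), penalty.alpha_mix)
            m = fit_penalised(Xtr, ytr, pen, task, groups=groups,
                              beta0=beta, b0=b, feature_names=names,
                              lipschitz=lip)
            m.impute_medians, m.standardise_mean, m.standardise_sd = med, mean, sd
            beta, b = m.coef, m.intercept
            vloss = _validation_loss(m, Xte_raw, yte)
            fold_losses[f, i] = vloss
            if vloss < best - 1e-12:
                best, rises = vloss, 0
            else:
                rises += 1
            # stop once clearly past an interior minimum (never on the flat
            # null-model head of the path, where nothing has entered yet)
            if rises >= 5 and best < fold_losses[f, 0] - 1e-12:
                fold_losses[f, i + 1:] = vloss  # carry forward, stop the path
                break
    used = ~np.all(np.isnan(fold_losses), axis=1)
    fold_losses = fold_losses[used]
    mean_loss = fold_losses.mean(axis=0)
    i_min = int(np.argmin(mean_loss))
    if not one_se or fold_losses.shape[0] < 2:
        return float(grid[i_min])
    se = fold_losses.std(axis=0, ddof=1) / np.sqrt(fold_losses.shape[0])
    within = mean_loss <= mean_loss[i_min] + se  # pointwise one-SE band
    return float(grid[int(np.argmax(within))])  # largest qualifying lambda


def group_recovery_benchmark(n_replicates: int = 50, seed: int = 0,
                             n_groups: int = 10, group_size: int = 5,
                             n_active_groups: int = 2, n: int = 200,
                             snr: float = 5.0, alpha_mix: float = 0.3,
                             n_points: int = 40) -> dict:
    """Support-recovery benchmark for the sparse-group lasso.

    Gaussian design with ``n_groups`` groups of ``group_size`` features, the
    first ``n_active_groups`` groups truly active (coefficients uniform in
    [0.5, 1.5] with random signs), and noise scaled to the requested
    signal-to-noise ratio.  Lambda is selected per replicate by inner 3-fold
    CV with the one-standard-error rule (CV-minimum lambda is
    prediction-optimal but systematically overselects groups).  A replicate
    succeeds when the nonzero groups contain every true group with at most
    ``n_active_groups`` false groups.
    """
    p = n_groups * group_size
    groups = {f"g{k}": list(range(group_size * k, group_size * (k + 1)))
              for k in range(n_groups)}
    true = {f"g{k}" for k in range(n_active_groups)}
    successes = 0
    details = []
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 9001, rep])
        X = rng.standard_normal((n, p))
        beta = np.zeros(p)
        act = n_active_groups * group_size
        beta[:act] = rng.uniform(0.5, 1.5, act) * rng.choice([-1.0, 1.0], act)
        signal = X @ beta
        y = signal + rng.normal(0.0, np.sqrt(signal.var() / snr), n)
        Xdf = pd.DataFrame(X, columns=[f"f{j}" for j in range(p)])
        Xdf.index = pd.MultiIndex.from_arrays(
            [[f"s{i}" for i in range(n)], [0] * n],
            names=["participant_id", "period_id"])
        pen = PenaltySpec("sparse_group_lasso", alpha_mix=alpha_mix)
        lam = select_lambda(Xdf, pd.Series(y, index=Xdf.index), pen,
                            "regression", groups, seed=seed * 131 + rep,
                            n_points=n_points, one_se=True)
        Xs, _, _, _ = _preprocess_train(X)
        model = fit_penalised(Xs, y, PenaltySpec("sparse_group_lasso", lam,
                                                 alpha_mix),
                              "regression", groups=groups)
        nz = {g for g, ix in groups.items()
              if np.linalg.norm(model.coef[ix]) > 0}
        ok = true <= nz and len(nz - true) <= n_active_groups
        successes += ok
        details.append({"replicate": rep, "lambda": lam,
                        "selected_groups": sorted(nz), "success": bool(ok)})
    return {"success_rate": successes / n_replicates, "n_replicates": n_replicates,
            "details": details}


def run_cv(matrix: FeatureMatrix, labels: pd.Series, penalty: PenaltySpec,
           task: str = "classification", k: int = 5, seed: int = 0,
           inner_k: int = 3, n_lambda: int = 20,
           fixed_lambda: float | None = None) -> CvReport:
    """Stratified subject-wise k-fold CV with majority-voted subject outcomes.

    ``labels`` maps participant_id -> label (0/1 for classification, real for
    regression).  Standardisation and median imputation are learned on each
    training fold only; lambda is chosen by inner subject-wise CV on the
    training participants unless ``fixed_lambda`` is given.
    """
    X = matrix.X
    pids = X.index.get_level_values("participant_id")
    upid = matrix.participants()
    missing = set(upid) - set(labels.index)
    if missing:
        raise ValueError(f"labels missing for participants: {sorted(missing)[:5]}")
    plab = labels.loc[upid].to_numpy()
    strat = plab.astype(int) if task == "classification" else np.zeros(upid.size, int)
    folds = stratified_subject_kfold(upid, strat, k, seed)
    groups = matrix.group_indices()
    fold_of = {pid: f for f, fold in enumerate(folds) for pid in fold}

    obs_rows = []
    fold_metrics = []
    chosen = []
    models = []
    y_all = pd.Series(labels.loc[pids].to_numpy(dtype=float), index=X.index)
    for f, test_pids in enumerate(folds):
        te = pids.isin(test_pids)
        ytr = y_all[~te]
        if task == "classification" and np.unique(ytr).size < 2:
            warnings.warn(f"fold {f}: single-class training labels; skipped")
            continue
        lam = fixed_lambda
        if lam is None:
            lam = select_lambda(X[~te], ytr, penalty, task, groups,
                                seed=seed * 1000 + f, inner_k=inner_k,
                                n_points=n_lambda)
        chosen.append(lam)
        pen = PenaltySpec(penalty.family, lam, penalty.alpha_mix)
        Xtr, med, mean, sd = _preprocess_train(X[~te].to_numpy(dtype=float))
        model = fit_penalised(Xtr, ytr.to_numpy(), pen, task, groups=groups,
                              feature_names=list(X.columns))
        model.impute_medians, model.standardise_mean, model.standardise_sd = med, mean, sd
        models.append(model)
        Xte = X[te].to_numpy(dtype=float)
        yte = y_all[te].to_numpy()
        if task == "classification":
            score = model.predict_proba(Xte)
            pred = (score >= 0.5).astype(int)
            fold_metrics.append(classification_metrics(yte, pred, score))
        else:
            score = model.decision_function(Xte)
            pred = score
            fold_metrics.append(regression_metrics(yte, pred))
        idx = X.index[te]
        for (pid, period), yv, sc, pr in zip(idx, yte, score, pred):
            obs_rows.append({"participant_id": pid, "period_id": period,
                             "fold": f, "y": yv, "score": sc, "pred": pr})

    obs = pd.DataFrame(obs_rows)
    subj_rows = []
    for pid, sub in obs.groupby("participant_id"):
        if task == "classification":
            pred = majority_vote(sub["pred"].to_numpy(), sub["score"].to_numpy())
        else:
            pred = float(sub["pred"].mean())
        subj_rows.append({"participant_id": pid, "y": sub["y"].iloc[0],
                          "pred": pred, "mean_score": float(sub["score"].mean())})
    subjects = pd.DataFrame(subj_rows)

    def med_iqr(values):
        vals = [v for v in values if v is not None]
        if not vals:
            return {"median": None, "iqr": None}
        q1, q2, q3 = np.percentile(vals, [25, 50, 75])
        return {"median": float(q2), "iqr": float(q3 - q1)}

    obs_metrics = {}
    if fold_metrics:
        for key in fold_metrics[0]:
            obs_metrics[key] = med_iqr([m[key] for m in fold_metrics])
    if task == "classification":
        subj_metrics = classification_metrics(subjects["y"], subjects["pred"],
                                              subjects["mean_score"])
    else:
        subj_metrics = regression_metrics(subjects["y"], subjects["pred"])
    return CvReport(fold_of, obs, subjects, obs_metrics, subj_metrics,
                    chosen, models)
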