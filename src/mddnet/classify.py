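"""Sparse logistic ensemble: L1-penalized logistic models in nested CV.

The marker is an ensemble of L1-penalized (LASSO) logistic regressions.
The penalized objective, with per-sample averaged log-loss and an
unpenalized intercept, is

    J(w, b) = -(1/n) sum_i log P(y_i | x_i; w, b) + lambda * ||w||_1 .

Training follows a nested cross-validation: the cohort is split into
``outer_folds`` stratified folds; within each training portion,
``subsamples`` age-matched class-balanced undersamples are drawn, and for
each subsample the penalty is tuned on a linear grid of ``n_lambda``
values from 0 to lambda_max by inner k-fold CV with the one-standard-error
rule.  The result is ``outer_folds x subsamples`` models (100 by default);
the ensemble's diagnostic probability is the mean of the member logistic
outputs and a participant is called a patient when it exceeds 0.5.

The convex fits are delegated to scikit-learn's liblinear coordinate
descent; the mapping between the averaged-loss penalty lambda and
scikit-learn's C is C = 1/(n*lambda).  liblinear technically penalizes the
intercept through its augmented-feature trick, so a large
``intercept_scaling`` is used to make that contribution negligible.
lambda >= lambda_max is handled in closed form (all-zero weights,
log-odds intercept), which is the exact optimum by the KKT conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .synth import MultiSiteDataset

__all__ = [
    "SparseLogisticModel",
    "ClassifierEnsemble",
    "lambda_max",
    "lambda_grid",
    "fit_sparse_logistic",
    "undersample_age_matched",
    "inner_cv_select_lambda",
    "train_ensemble",
    "predict_probability",
]

_INTERCEPT_SCALING = 1e3


@dataclass
class SparseLogisticModel:
    """One fitted L1-logistic member, with its training standardization."""

    w: np.ndarray
    intercept: float
    lambda_selected: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.w)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.w.size:
            raise ValueError(f"expected {self.w.size} features, got {X.shape[1]}")
        z = (X - self.feature_mean) / self.feature_scale
        return expit(z @ self.w + self.intercept)


@dataclass
class ClassifierEnsemble:
    """outer_folds x subsamples fitted members plus the fold assignment."""

    models: list[list[SparseLogisticModel]]   # [fold][subsample]
    fold_assignment: np.ndarray               # participant -> outer fold, -1 if unused
    seed: int
    cv_probabilities: np.ndarray | None = None  # held-out fold predictions

    @property
    def n_models(self) -> int:
        return sum(len(f) for f in self.models)

    def flat_models(self) -> list[SparseLogisticModel]:
        return [m for fold in self.models for m in fold]


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one row per label")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("y must contain both classes, coded 0/1")
    return X, y


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty whose unique optimum is the all-zero weight vector.

    With the intercept at the null log-odds the KKT stationarity condition
    gives lambda_max = max_k |(1/n) sum_i x_ik (y_i - ybar)|.
    """
    X, y = _validate_xy(X, y)
    return float(np.abs(X.T @ (y - y.mean())).max() / y.size)


def lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int = 25) -> np.ndarray:
    """``n_lambda`` equally spaced penalties on [0, lambda_max], descending."""
    if n_lambda < 1:
        raise ValueError("n_lambda must be >= 1")
    lmax = lambda_max(X, y)
    return np.linspace(lmax, 0.0, n_lambda)


def fit_sparse_logistic(X: np.ndarray, y: np.ndarray, lam: float,
                        tol: float = 1e-8, max_iter: int = 5000) -> SparseLogisticModel:
    """Minimize the averaged-loss L1 objective at penalty ``lam``.

    Features are used as given (standardize upstream); the returned model
    records an identity standardization.  ``lam >= lambda_max`` returns the
    exact closed-form optimum.
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    X, y = _validate_xy(X, y)
    n, p = X.shape
    mean = np.zeros(p)
    scale = np.ones(p)
    if lam > 0 and lam >= lambda_max(X, y) - 1e-15:
        ybar = y.mean()
        return SparseLogisticModel(w=np.zeros(p), intercept=float(np.log(ybar / (1 - ybar))),
                                   lambda_selected=lam, feature_mean=mean, feature_scale=scale)
    if lam == 0:
        clf = LogisticRegression(C=np.inf, solver="lbfgs", tol=tol, max_iter=max_iter)
    else:
        clf = LogisticRegression(l1_ratio=1.0, C=1.0 / (n * lam), solver="liblinear",
                                 tol=tol, max_iter=max_iter,
                                 intercept_scaling=_INTERCEPT_SCALING, random_state=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    return SparseLogisticModel(w=clf.coef_.ravel().copy(), intercept=float(clf.intercept_[0]),
                               lambda_selected=float(lam), feature_mean=mean, feature_scale=scale)


def logistic_objective(model: SparseLogisticModel, X: np.ndarray, y: np.ndarray,
                       lam: float) -> float:
    """J(w, b) at the model's parameters (for diagnostics and oracles)."""
    z = X @ model.w + model.intercept
    loss = np.logaddexp(0.0, z) - y * z
    return float(loss.mean() + lam * np.abs(model.w).sum())


def undersample_age_matched(y: np.ndarray, age: np.ndarray, target_per_class: int | None = None,
                            seed: int = 0, age_tolerance: float = 1.0,
                            cap: int = 125) -> np.ndarray:
    """Class-balanced subset with matched mean ages, by greedy nearest-age pairing.

    Anchors are a seeded random draw from the minority class; each anchor
    takes the closest-aged unused member of the majority class.  If the
    resulting mean-age gap exceeds ``age_tolerance`` (years), the pairs
    contributing most to the gap are dropped (keeping the classes equal)
    until the tolerance is met; if that would shrink the subset below half
    the target, a matching error reports the best achievable gap.
    """
    y = np.asarray(y).astype(int).ravel()
    age = np.asarray(age, dtype=float).ravel()
    if y.size != age.size:
        raise ValueError("y and age must have equal lengths")
    idx0, idx1 = np.flatnonzero(y == 0), np.flatnonzero(y == 1)
    if idx0.size == 0 or idx1.size == 0:
        raise ValueError("both classes must be present")
    target = min(idx0.size, idx1.size, cap if target_per_class is None else target_per_class)
    rng = np.random.default_rng(seed)
    minority, majority = (idx1, idx0) if idx1.size <= idx0.size else (idx0, idx1)
    anchors = rng.permutation(minority)[:target]
    avail = np.ones(majority.size, dtype=bool)
    maj_ages = age[majority]
    partners = np.empty(target, dtype=int)
    for i, a in enumerate(anchors):
        cand = np.flatnonzero(avail)
        pick = cand[np.argmin(np.abs(maj_ages[cand] - age[a]))]
        avail[pick] = False
        partners[i] = majority[pick]
    floor = max(2, target // 2)
    keep = np.ones(target, dtype=bool)
    diffs = age[anchors] - age[partners]
    while True:
        gap = diffs[keep].mean()
        if abs(gap) <= age_tolerance:
            break
        if keep.sum() <= floor:
            raise ValueError(f"age matching failed: best achievable mean-age gap "
                             f"{abs(gap):.2f} exceeds tolerance {age_tolerance}")
        # drop the kept pair pushing hardest in the direction of the gap
        cand = np.flatnonzero(keep)
        keep[cand[np.argmax(np.sign(gap) * diffs[cand])]] = False
    return np.sort(np.concatenate([anchors[keep], partners[keep]]))


def inner_cv_select_lambda(X: np.ndarray, y: np.ndarray, grid: np.ndarray,
                           k_inner: int = 10, seed: int = 0, rule: str = "se",
                           tol: float = 1e-5) -> float:
    """One-standard-error lambda selection by inner k-fold CV deviance.

    Per fold and per grid value the model is fit on the training part and
    scored by mean held-out deviance (2x negative average log-likelihood).
    The selected lambda is the largest grid value whose mean CV error does
    not exceed the minimum mean error plus the error spread at the
    minimizer — the spread is SD over folds divided by sqrt(k) for
    ``rule='se'`` (the default reading of the one-SE rule) or the raw SD
    for ``rule='sd'``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    if k_inner < 2:
        raise ValueError("k_inner must be >= 2")
    if rule not in ("se", "sd"):
        raise ValueError("rule must be 'se' or 'sd'")
    X, y = _validate_xy(X, y)
    order = np.argsort(grid)[::-1]
    grid_desc = grid[order]
    skf = StratifiedKFold(n_splits=k_inner, shuffle=True, random_state=seed)
    errors = np.empty((k_inner, grid.size))
    for f, (tr, va) in enumerate(skf.split(X, y)):
        lmax_fold = lambda_max(X[tr], y[tr])
        for g, lam in enumerate(grid_desc):
            if lam > 0 and lam >= lmax_fold:
                ybar = y[tr].mean()
                prob = np.full(va.size, ybar)
            else:
                model = fit_sparse_logistic(X[tr], y[tr], lam, tol=tol, max_iter=1000)
                prob = model.predict_proba(X[va])
            prob = np.clip(prob, 1e-12, 1 - 1e-12)
            yv = y[va]
            errors[f, g] = -2.0 * np.mean(yv * np.log(prob) + (1 - yv) * np.log(1 - prob))
    mean_err = errors.mean(axis=0)
    best = int(np.argmin(mean_err))
    spread = errors[:, best].std(ddof=1)
    if rule == "se":
        spread /= np.sqrt(k_inner)
    ok = mean_err <= mean_err[best] + spread
    return float(grid_desc[np.flatnonzero(ok)[0]])  # grid is descending: first ok = largest lambda


def train_ensemble(data: MultiSiteDataset, outer_folds: int = 10, subsamples: int = 10,
                   seed: int = 0, n_lambda: int = 25, k_inner: int = 10,
                   undersample_cap: int = 125, age_tolerance: float = 1.0,
                   inner_tol: float = 1e-5, final_tol: float = 1e-7,
                   labels: np.ndarray | None = None) -> ClassifierEnsemble:
    """Nested-CV training of the outer_folds x subsamples ensemble.

    Each member is trained only on its outer-fold training portion: the
    held-out fold never influences undersampling, standardization, lambda
    selection or the final fit.  Held-out predictions (each fold scored by
    its own ``subsamples`` members) are stored on the ensemble.
    ``labels`` overrides the dataset diagnosis (used by permutation tests).
    """
    y = data.y if labels is None else np.asarray(labels).astype(int).ravel()
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("both classes must be present")
    X, age = data.connectivity, data.age
    skf = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    fold_assignment = np.full(y.size, -1, dtype=int)
    cv_prob = np.full(y.size, np.nan)
    models: list[list[SparseLogisticModel]] = []
    rng = np.random.default_rng(seed)
    for f, (tr, te) in enumerate(skf.split(X, y)):
        fold_assignment[te] = f
        if len(set(y[tr])) < 2 or len(set(y[te])) < 2:
            raise ValueError(f"outer fold {f} lacks a class")
        fold_models: list[SparseLogisticModel] = []
        for s in range(subsamples):
            sub_seed = int(rng.integers(2 ** 31))
            sub = tr[undersample_age_matched(y[tr], age[tr], seed=sub_seed,
                                             age_tolerance=age_tolerance, cap=undersample_cap)]
            Xs, ys = X[sub], y[sub]
            mu = Xs.mean(axis=0)
            sd = Xs.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            Zs = (Xs - mu) / sd
            grid = lambda_grid(Zs, ys, n_lambda)
            lam = inner_cv_select_lambda(Zs, ys, grid, k_inner=k_inner,
                                         seed=sub_seed, tol=inner_tol)
            model = fit_sparse_logistic(Zs, ys, lam, tol=final_tol, max_iter=5000)
            model.feature_mean, model.feature_scale = mu, sd
            fold_models.append(model)
        models.append(fold_models)
        fold_prob = np.mean([m.predict_proba(X[te]) for m in fold_models], axis=0)
        cv_prob[te] = fold_prob
    return ClassifierEnsemble(models=models, fold_assignment=fold_assignment,
                              seed=seed, cv_probabilities=cv_prob)


def predict_probability(ensemble: ClassifierEnsemble, X: np.ndarray) -> np.ndarray:
    """Mean member logistic output; classify MDD when strictly above 0.5."""
    members = ensemble.flat_models()
    if not members:
        raise ValueError("ensemble has no members")
    return np.mean([m.predict_proba(np.asarray(X, dtype=float)) for m in members], axis=0)
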