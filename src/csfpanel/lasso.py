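"""Cross-validated LASSO logistic regression and stability selection.

:class:`CVLassoClassifier` fits an l1-penalized binomial logistic
regression over a 100-point log-spaced lambda grid, choosing lambda at
the minimum 5-fold cross-validated deviance (ties toward the larger,
sparser lambda).  Features are standardized internally on the training
data; the intercept is unpenalized.

:func:`stability_lasso` re-runs the lambda selection R times on a fixed
train/test split, varying only the cross-validation fold seed, and
reports each protein's selection frequency (% of the R models in which
its coefficient is nonzero) together with every model's test-set AUC.
Since the training data never change, the full-path coefficients are
computed once and each repetition reads its own lambda_min from that
shared path -- the exact semantics of repeated ``cv.glmnet`` calls with
different seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.feature_selection import SelectorMixin

from ._lasso_engine import cv_fold_deviance, logistic_lasso_path
from .cohort import stratified_split
from .metrics import roc_auc

__all__ = ["LassoConfig", "CVLassoClassifier", "StabilityResult",
           "stability_lasso", "StabilityLassoSelector", "cv_lasso_fit"]


@dataclass
class LassoConfig:
    cv_folds: int = 5
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-3
    tol: float = 1e-6       # full-path coefficient tolerance
    cv_tol: float = 3e-4    # fold-path tolerance (only the CV curve is needed)
    max_outer: int = 25

    def validate(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_lambdas < 10:
            raise ValueError("n_lambdas must be >= 10")


def _standardize(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd


def _lambda_grid(Xs, y, n_lambdas, min_ratio):
    n = len(y)
    lam_max = np.abs(Xs.T @ (y - y.mean())).max() / n
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, min_ratio * lam_max, n_lambdas)


def _fold_vector(n, nfold, y, rng, max_attempts=10):
    """Shuffled balanced fold assignment; refolds (deterministic sub-streams)
    until every fold's training part contains both classes."""
    for _ in range(max_attempts):
        folds = rng.permutation(np.arange(n) % nfold).astype(np.int64)
        ok = True
        for f in range(nfold):
            cls = np.unique(y[folds != f])
            if len(cls) < 2:
                ok = False
                break
        if ok:
            return folds
    raise RuntimeError(
        f"could not build {nfold} folds with two classes in every training "
        f"part after {max_attempts} attempts")


class CVLassoClassifier(BaseEstimator, ClassifierMixin):
    """l1-penalized logistic regression with lambda chosen by CV deviance.

    Parameters mirror :class:`LassoConfig`; ``cv_seed`` controls only the
    fold assignment.  Fitted attributes: ``coef_``, ``intercept_``,
    ``lambda_``, ``lambda_index_``, ``lambdas_``, ``cv_deviance_``,
    ``selected_`` (boolean mask of nonzero coefficients).
    """

    def __init__(self, cv_folds: int = 5, n_lambdas: int = 100,
                 lambda_min_ratio: float = 1e-3, tol: float = 1e-6,
                 cv_tol: float = 3e-4, max_outer: int = 25, cv_seed: int = 0):
        self.cv_folds = cv_folds
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.tol = tol
        self.cv_tol = cv_tol
        self.max_outer = max_outer
        self.cv_seed = cv_seed

    def fit(self, X, y):
        X = np.ascontiguousarray(np.asarray(X, float))
        y = np.asarray(y, float)
        self.classes_ = np.unique(y).astype(int)
        if len(self.classes_) != 2:
            raise ValueError("binary labels required")
        cfg = LassoConfig(self.cv_folds, self.n_lambdas, self.lambda_min_ratio,
                          self.tol, self.cv_tol, self.max_outer)
        cfg.validate()
        Xs, self.center_, self.scale_ = _standardize(X)
        self.lambdas_ = _lambda_grid(Xs, y, self.n_lambdas, self.lambda_min_ratio)
        rng = np.random.default_rng(self.cv_seed)
        folds = _fold_vector(len(y), self.cv_folds, y, rng)
        self.cv_deviance_ = cv_fold_deviance(
            np.ascontiguousarray(Xs), y, self.lambdas_, folds, self.cv_folds,
            self.cv_tol, self.max_outer)
        # argmin with ties toward larger (earlier, sparser) lambda
        self.lambda_index_ = int(np.argmin(self.cv_deviance_))
        self.lambda_ = float(self.lambdas_[self.lambda_index_])
        b0s, betas = logistic_lasso_path(
            np.ascontiguousarray(Xs.T), y, self.lambdas_, self.tol, self.max_outer)
        self.path_intercepts_ = b0s
        self.path_coefs_ = betas
        self.coef_ = betas[self.lambda_index_].copy()
        self.intercept_ = float(b0s[self.lambda_index_])
        self.selected_ = self.coef_ != 0.0
        return self

    def decision_function(self, X):
        X = np.asarray(X, float)
        Xs = (X - self.center_) / self.scale_
        return self.intercept_ + Xs @ self.coef_

    def predict_proba(self, X):
        eta = np.clip(self.decision_function(X), -30, 30)
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.decision_function(X) >= 0).astype(int)


def cv_lasso_fit(X_train, y_train, config: Optional[LassoConfig] = None,
                 cv_seed: int = 0) -> CVLassoClassifier:
    """Functional wrapper: fit a :class:`CVLassoClassifier`."""
    cfg = config or LassoConfig()
    return CVLassoClassifier(
        cv_folds=cfg.cv_folds, n_lambdas=cfg.n_lambdas,
        lambda_min_ratio=cfg.lambda_min_ratio, tol=cfg.tol, cv_tol=cfg.cv_tol,
        max_outer=cfg.max_outer, cv_seed=cv_seed).fit(X_train, y_train)


@dataclass
class StabilityResult:
    selection_frequency: pd.Series   # % of R models with nonzero coefficient
    test_aucs: np.ndarray            # (R,) fixed-test-set AUC per model
    model_selections: np.ndarray     # (R, p) bool, per-model selected sets
    lambda_indices: np.ndarray       # (R,) chosen grid index per model
    seeds: np.ndarray                # (R,) CV seeds used
    R: int

    def summary(self) -> dict:
        return {
            "R": int(self.R),
            "auc_min": float(self.test_aucs.min()),
            "auc_max": float(self.test_aucs.max()),
            "n_selected_ever": int((self.selection_frequency > 0).sum()),
        }


def stability_lasso(X_train, y_train, X_test, y_test, R: int = 1000,
                    config: Optional[LassoConfig] = None,
                    base_seed: int = 0,
                    feature_names: Optional[Sequence[str]] = None) -> StabilityResult:
    """Selection frequencies over R re-seeded CV-LASSO fits on one split."""
    if R < 1:
        raise ValueError("R must be >= 1")
    cfg = config or LassoConfig()
    cfg.validate()
    X_train = np.ascontiguousarray(np.asarray(X_train, float))
    X_test = np.asarray(X_test, float)
    y_train = np.asarray(y_train, float)
    y_test = np.asarray(y_test, int)
    n, p = X_train.shape
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(p)]

    Xs, mu, sd = _standardize(X_train)
    lambdas = _lambda_grid(Xs, y_train, cfg.n_lambdas, cfg.lambda_min_ratio)
    b0s, betas = logistic_lasso_path(
        np.ascontiguousarray(Xs.T), y_train, lambdas, cfg.tol, cfg.max_outer)
    Xts = (X_test - mu) / sd

    seeds = (base_seed + np.arange(R)) % (2 ** 31)
    lam_idx = np.empty(R, int)
    aucs = np.empty(R)
    selections = np.zeros((R, p), bool)
    XsC = np.ascontiguousarray(Xs)
    for r in range(R):
        rng = np.random.default_rng(int(seeds[r]))
        folds = _fold_vector(n, cfg.cv_folds, y_train, rng)
        dev = cv_fold_deviance(XsC, y_train, lambdas, folds, cfg.cv_folds,
                               cfg.cv_tol, cfg.max_outer)
        li = int(np.argmin(dev))
        lam_idx[r] = li
        selections[r] = betas[li] != 0.0
        scores = b0s[li] + Xts @ betas[li]
        aucs[r] = roc_auc(scores, y_test).auc
    freq = pd.Series(100.0 * selections.mean(axis=0), index=list(feature_names),
                     name="lasso_pct_selected")
    return StabilityResult(selection_frequency=freq, test_aucs=aucs,
                           model_selections=selections, lambda_indices=lam_idx,
                           seeds=seeds, R=R)


class StabilityLassoSelector(BaseEstimator, SelectorMixin):
    """Feature selector: stability selection via re-seeded CV-LASSO.

    ``fit(X, y)`` makes an internal stratified train/test split (the split
    seed is ``base_seed``), runs :func:`stability_lasso`, and exposes the
    proteins whose selection frequency reaches ``freq_min_pct`` through
    the standard ``get_support`` / ``transform`` API.
    """

    def __init__(self, R: int = 1000, freq_min_pct: float = 20.0,
                 train_fraction: float = 2 / 3, base_seed: int = 0,
                 cv_folds: int = 5, n_lambdas: int = 100,
                 lambda_min_ratio: float = 1e-3, tol: float = 1e-6,
                 cv_tol: float = 3e-4, max_outer: int = 25):
        self.R = R
        self.freq_min_pct = freq_min_pct
        self.train_fraction = train_fraction
        self.base_seed = base_seed
        self.cv_folds = cv_folds
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.tol = tol
        self.cv_tol = cv_tol
        self.max_outer = max_outer

    def fit(self, X, y):
        names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        if names is not None:
            self.feature_names_in_ = np.asarray(names, dtype=object)
        Xa = np.asarray(X, float)
        y = np.asarray(y, int)
        split = stratified_split(y, self.train_fraction, seed=self.base_seed)
        cfg = LassoConfig(self.cv_folds, self.n_lambdas, self.lambda_min_ratio,
                          self.tol, self.cv_tol, self.max_outer)
        self.split_ = split
        self.result_ = stability_lasso(
            Xa[split.train_idx], y[split.train_idx],
            Xa[split.test_idx], y[split.test_idx],
            R=self.R, config=cfg, base_seed=self.base_seed,
            feature_names=names)
        self.selection_frequency_ = self.result_.selection_frequency
        self.test_aucs_ = self.result_.test_aucs
        self.n_features_in_ = Xa.shape[1]
        return self

    def _get_support_mask(self):
        return (self.selection_frequency_.to_numpy() >= self.freq_min_pct)
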