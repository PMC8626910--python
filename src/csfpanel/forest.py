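"""Random-forest importance ensembles with OOB evaluation.

A single forest is a fully grown classification random forest
(bootstrap, Gini, ``mtry`` features per split).  Importance is the mean
decrease in accuracy (mda): for each tree, the drop in out-of-bag
accuracy when one protein's OOB values are permuted.  By default the
per-forest mda is reported on the scaled variant -- mean decrease divided
by its standard error across trees -- whose magnitudes are comparable
across forest sizes in the usual published range; the raw accuracy scale
is selectable.  :func:`forest_ensemble` averages the per-forest mda over
R re-seeded forests and records each forest's OOB-vote AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from ._forest_engine import forest_oob_run
from .metrics import oob_auc as _oob_auc

__all__ = ["ForestConfig", "single_forest", "tune_forest", "forest_ensemble",
           "ForestEnsembleResult", "ForestImportanceEnsemble"]


@dataclass
class ForestConfig:
    n_trees: int = 500
    mtry: Optional[int] = None          # default floor(sqrt(p))
    importance_scale: str = "scaled"    # "scaled" (mda / SE) or "raw"

    def resolved_mtry(self, p: int) -> int:
        m = self.mtry if self.mtry is not None else int(np.floor(np.sqrt(p)))
        return int(min(max(m, 1), p))

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.importance_scale not in ("scaled", "raw"):
            raise ValueError("importance_scale must be 'scaled' or 'raw'")


@dataclass
class SingleForestResult:
    mda: np.ndarray          # per-protein importance (scale per config)
    mda_raw: np.ndarray      # unscaled mean accuracy decrease
    oob_votes: np.ndarray    # per-sample fraction of OOB votes for class 1
    oob_error: float         # misclassification of OOB votes at 0.5
    oob_auc: float


def single_forest(X, y, config: ForestConfig, seed: int = 0,
                  warn_degenerate: bool = True) -> SingleForestResult:
    """Fit one forest; returns importances and OOB vote statistics."""
    config.validate()
    X = np.ascontiguousarray(np.asarray(X, float))
    y = np.ascontiguousarray(np.asarray(y), dtype=np.int64)
    n, p = X.shape
    mtry = config.resolved_mtry(p)
    mean_d, sd_d, vote1, n_oob = forest_oob_run(
        X, y, int(config.n_trees), mtry, int(seed) % (2 ** 31))
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(sd_d > 0,
                          mean_d / (sd_d / np.sqrt(config.n_trees)), mean_d)
    if warn_degenerate and np.any((sd_d == 0) & (mean_d == 0)):
        k = int(np.sum((sd_d == 0) & (mean_d == 0)))
        warnings.warn(f"{k} protein(s) unused by every tree; mda set to 0")
    votes = np.where(n_oob > 0, vote1 / np.maximum(n_oob, 1), np.nan)
    valid = np.isfinite(votes)
    pred = votes[valid] >= 0.5
    oob_err = float(np.mean(pred != (y[valid] == 1)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        auc = _oob_auc(votes, y)
    return SingleForestResult(
        mda=scaled if config.importance_scale == "scaled" else mean_d,
        mda_raw=mean_d, oob_votes=votes, oob_error=oob_err, oob_auc=float(auc))


def tune_forest(X, y, ntree_grid: Sequence[int] = (500,), seed: int = 0,
                mtry_step: float = 2.0, improve_tol: float = 0.05,
                ) -> Tuple[ForestConfig, List[dict]]:
    """Choose forest size and mtry by OOB error.

    ``n_trees`` is the grid value minimizing OOB error (ties toward the
    smallest).  ``mtry`` starts at floor(sqrt(p)) and is doubled/halved by
    ``mtry_step``, a step being accepted only while it improves OOB error
    by more than ``improve_tol`` relative -- the classic forest tuning
    search.  Returns the config and the evaluation trace.
    """
    if len(ntree_grid) == 0:
        raise ValueError("ntree_grid is empty")
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise ValueError("two classes required")
    p = np.asarray(X).shape[1]
    trace: List[dict] = []

    def oob_err(n_trees, mtry):
        res = single_forest(X, y, ForestConfig(n_trees=n_trees, mtry=mtry),
                            seed=seed, warn_degenerate=False)
        return res.oob_error

    errs = []
    for nt in ntree_grid:
        e = oob_err(int(nt), None)
        errs.append(e)
        trace.append({"stage": "ntree", "n_trees": int(nt),
                      "mtry": int(np.floor(np.sqrt(p))), "oob_error": e})
    best_nt = int(ntree_grid[int(np.argmin(errs))])
    best_err = float(np.min(errs))

    start = int(np.floor(np.sqrt(p)))
    best_mtry = start
    for direction in (1, -1):
        mtry = start
        err_here = best_err
        while True:
            nxt = int(round(mtry * mtry_step)) if direction == 1 else max(
                1, int(round(mtry / mtry_step)))
            if nxt == mtry or nxt > p:
                break
            e = oob_err(best_nt, nxt)
            trace.append({"stage": "mtry", "n_trees": best_nt,
                          "mtry": nxt, "oob_error": e})
            if e < err_here * (1 - improve_tol):
                err_here = e
                mtry = nxt
                if e < best_err:
                    best_err = e
                    best_mtry = nxt
            else:
                break
    return ForestConfig(n_trees=best_nt, mtry=best_mtry), trace


@dataclass
class ForestEnsembleResult:
    mean_mda: pd.Series        # per-protein mda averaged over R forests
    oob_aucs: np.ndarray       # (R,)
    oob_errors: np.ndarray     # (R,)
    per_forest_mda: np.ndarray  # (R, p)
    seeds: np.ndarray
    R: int
    config: ForestConfig

    def summary(self) -> dict:
        return {
            "R": int(self.R),
            "oob_auc_min": float(self.oob_aucs.min()),
            "oob_auc_max": float(self.oob_aucs.max()),
            "oob_error_mean": float(self.oob_errors.mean()),
        }


def forest_ensemble(X, y, config: Optional[ForestConfig] = None, R: int = 1000,
                    base_seed: int = 0,
                    feature_names: Optional[Sequence[str]] = None,
                    ) -> ForestEnsembleResult:
    """Mean mda over R forests differing only in their RNG seed."""
    if R < 1:
        raise ValueError("R must be >= 1")
    cfg = config or ForestConfig()
    cfg.validate()
    Xa = np.ascontiguousarray(np.asarray(X, float))
    p = Xa.shape[1]
    if feature_names is None:
        feature_names = list(X.columns) if isinstance(X, pd.DataFrame) \
            else [f"f{j}" for j in range(p)]
    seeds = (base_seed + np.arange(R)) % (2 ** 31)
    per = np.empty((R, p))
    aucs = np.empty(R)
    errs = np.empty(R)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(R):
            res = single_forest(Xa, y, cfg, seed=int(seeds[r]),
                                warn_degenerate=False)
            per[r] = res.mda
            aucs[r] = res.oob_auc
            errs[r] = res.oob_error
    mean = pd.Series(per.mean(axis=0), index=list(feature_names),
                     name="mean_mda")
    return ForestEnsembleResult(mean_mda=mean, oob_aucs=aucs, oob_errors=errs,
                                per_forest_mda=per, seeds=seeds, R=R, config=cfg)


class ForestImportanceEnsemble(BaseEstimator, SelectorMixin):
    """Selector exposing proteins whose ensemble mean mda exceeds a cut-off."""

    def __init__(self, R: int = 1000, mda_min: float = 8.0,
                 n_trees: int = 500, mtry: Optional[int] = None,
                 importance_scale: str = "scaled", base_seed: int = 0):
        self.R = R
        self.mda_min = mda_min
        self.n_trees = n_trees
        self.mtry = mtry
        self.importance_scale = importance_scale
        self.base_seed = base_seed

    def fit(self, X, y):
        cfg = ForestConfig(n_trees=self.n_trees, mtry=self.mtry,
                           importance_scale=self.importance_scale)
        self.result_ = forest_ensemble(X, np.asarray(y, int), cfg, R=self.R,
                                       base_seed=self.base_seed)
        self.mean_mda_ = self.result_.mean_mda
        self.oob_aucs_ = self.result_.oob_aucs
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def _get_support_mask(self):
        return self.mean_mda_.to_numpy() > self.mda_min
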