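"""Consensus panel calling from the two selection engines.

A protein enters the *union* panel if it passes either evidence
threshold (LASSO selection frequency >= ``lasso_freq_min`` percent, or
ensemble mean mda > ``mda_min``) and the *core* panel if it passes both.
The evidence table mirrors the published panel tables: one row per
protein with both statistics and the union/core flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .forest import ForestEnsembleResult, ForestImportanceEnsemble
from .lasso import StabilityLassoSelector, StabilityResult

__all__ = ["ConsensusThresholds", "PanelSelection", "consensus_panel",
           "ConsensusPanelSelector"]


@dataclass
class ConsensusThresholds:
    lasso_freq_min: float = 20.0  # percent of models
    mda_min: float = 8.0

    def validate(self) -> None:
        if not 0 <= self.lasso_freq_min <= 100:
            raise ValueError("lasso_freq_min must be in [0, 100]")


@dataclass
class PanelSelection:
    union: List[str]
    core: List[str]
    evidence: pd.DataFrame  # protein, lasso_pct_selected, mean_mda, flags
    thresholds: ConsensusThresholds


def _freq_series(stability) -> pd.Series:
    if isinstance(stability, StabilityResult):
        return stability.selection_frequency
    return pd.Series(stability)


def _mda_series(ensemble) -> pd.Series:
    if isinstance(ensemble, ForestEnsembleResult):
        return ensemble.mean_mda
    return pd.Series(ensemble)


def consensus_panel(stability, ensemble,
                    thresholds: Optional[ConsensusThresholds] = None,
                    ) -> PanelSelection:
    """Combine selection frequencies and mean mda into union/core panels.

    ``stability`` and ``ensemble`` may be the result objects of the two
    engines or plain per-protein mappings/Series; the two protein sets
    must match exactly.
    """
    thr = thresholds or ConsensusThresholds()
    thr.validate()
    freq = _freq_series(stability)
    mda = _mda_series(ensemble)
    sym = set(freq.index).symmetric_difference(mda.index)
    if sym:
        raise ValueError(
            f"protein sets differ between the two results: {sorted(sym)}")
    mda = mda.reindex(freq.index)
    pass_lasso = freq >= thr.lasso_freq_min
    pass_mda = mda > thr.mda_min
    in_union = pass_lasso | pass_mda
    in_core = pass_lasso & pass_mda
    evidence = pd.DataFrame({
        "protein": freq.index,
        "lasso_pct_selected": freq.to_numpy(),
        "mean_mda": mda.to_numpy(),
        "pass_lasso": pass_lasso.to_numpy(),
        "pass_mda": pass_mda.to_numpy(),
        "in_union": in_union.to_numpy(),
        "in_core": in_core.to_numpy(),
    }).reset_index(drop=True)
    return PanelSelection(
        union=sorted(freq.index[in_union]),
        core=sorted(freq.index[in_core]),
        evidence=evidence, thresholds=thr)


class ConsensusPanelSelector(BaseEstimator, SelectorMixin):
    """Meta-selector running both engines and intersecting their calls.

    ``get_support()`` returns the union mask by default; pass
    ``use_core=True`` at construction for the core (both-methods) panel.
    """

    def __init__(self, R: int = 1000, lasso_freq_min: float = 20.0,
                 mda_min: float = 8.0, use_core: bool = True,
                 train_fraction: float = 2 / 3, n_trees: int = 500,
                 mtry: Optional[int] = None, base_seed: int = 0):
        self.R = R
        self.lasso_freq_min = lasso_freq_min
        self.mda_min = mda_min
        self.use_core = use_core
        self.train_fraction = train_fraction
        self.n_trees = n_trees
        self.mtry = mtry
        self.base_seed = base_seed

    def fit(self, X, y):
        self.lasso_ = StabilityLassoSelector(
            R=self.R, freq_min_pct=self.lasso_freq_min,
            train_fraction=self.train_fraction,
            base_seed=self.base_seed).fit(X, y)
        self.forest_ = ForestImportanceEnsemble(
            R=self.R, mda_min=self.mda_min, n_trees=self.n_trees,
            mtry=self.mtry, base_seed=self.base_seed).fit(X, y)
        self.panel_ = consensus_panel(
            self.lasso_.result_, self.forest_.result_,
            ConsensusThresholds(self.lasso_freq_min, self.mda_min))
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def _get_support_mask(self):
        col = "in_core" if self.use_core else "in_union"
        return self.panel_.evidence[col].to_numpy()
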