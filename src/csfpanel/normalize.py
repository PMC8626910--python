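"""Two-step signal normalization for bead-array intensity data.

Step 1 (:class:`DriftNormalizer`) removes the monotone intensity drift
that accumulates with readout order: per protein, a robust linear
regression (Huber M-estimation) of signal on readout position is fitted
and the recentred residuals are added back to the protein's median
signal, so the corrected values keep each protein's median level.

Step 2 (:class:`PlateNormalizer`) equalizes per-protein medians across
assay plates by multiplicative scaling on the raw intensity scale.

Both are scikit-learn style transformers; the module-level
``drift_normalize`` / ``plate_normalize`` functions are thin wrappers for
one-shot use.
"""

from __future__ import annotations

import json
import warnings
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["DriftNormalizer", "PlateNormalizer", "drift_normalize", "plate_normalize"]


def _as_frame(X):
    if isinstance(X, pd.DataFrame):
        return X, True
    return pd.DataFrame(np.asarray(X, float)), False


class DriftNormalizer(BaseEstimator, TransformerMixin):
    """Robust readout-order drift correction.

    Per protein, fit ``signal ~ readout_position`` by a Huber M-estimator
    (tuning constant 1.345, MAD scale, iteratively reweighted least
    squares) and replace the signal by

        residual - median(residual) + median(signal),

    i.e. the drift-free component recentred so that the protein's median
    is preserved exactly.  Proteins with a constant value are returned
    recentred to their median with a warning.

    Parameters
    ----------
    tuning_const : Huber threshold in scale units (1.345 gives 95%%
        efficiency under normal errors).
    max_iter, tol : IRLS iteration cap and coefficient convergence
        tolerance.
    log_scale : fit and correct on log-transformed signals (the corrected
        values are exponentiated back).
    """

    def __init__(self, tuning_const: float = 1.345, max_iter: int = 50,
                 tol: float = 1e-8, log_scale: bool = False):
        self.tuning_const = tuning_const
        self.max_iter = max_iter
        self.tol = tol
        self.log_scale = log_scale

    def fit(self, X, y=None, readout_order=None):
        if readout_order is None:
            raise ValueError("readout_order is required")
        Xf, _ = _as_frame(X)
        t = np.asarray(readout_order, float)
        if len(t) != len(Xf):
            raise ValueError("readout_order length does not match samples")
        if sorted(np.asarray(readout_order, int)) != list(range(1, len(Xf) + 1)):
            raise ValueError("readout_order must be a permutation of 1..n_samples")
        V = Xf.to_numpy(float)
        if not np.all(np.isfinite(V)):
            raise ValueError("signal matrix contains non-finite values")
        if self.log_scale:
            V = np.log(V)
        design = sm.add_constant(t)
        norm = sm.robust.norms.HuberT(t=self.tuning_const)
        p = V.shape[1]
        self.intercepts_ = np.empty(p)
        self.slopes_ = np.empty(p)
        self.medians_ = np.median(V, axis=0)
        self.resid_medians_ = np.empty(p)
        self.n_iter_ = np.zeros(p, int)
        constant_cols = []
        for j in range(p):
            v = V[:, j]
            if np.ptp(v) == 0.0:
                constant_cols.append(Xf.columns[j])
                self.intercepts_[j] = v[0]
                self.slopes_[j] = 0.0
                self.resid_medians_[j] = 0.0
                continue
            res = sm.RLM(v, design, M=norm).fit(
                maxiter=self.max_iter, tol=self.tol, conv="coefs")
            self.intercepts_[j], self.slopes_[j] = res.params
            self.resid_medians_[j] = np.median(v - res.fittedvalues)
            self.n_iter_[j] = res.fit_history.get("iteration", 0) if hasattr(
                res, "fit_history") else 0
        if constant_cols:
            warnings.warn(
                f"constant signal for {len(constant_cols)} protein(s) "
                f"(e.g. {constant_cols[:3]}); drift fit degenerate, "
                "recentred to median only")
        self.columns_ = list(Xf.columns)
        return self

    def transform(self, X, readout_order=None):
        if readout_order is None:
            raise ValueError("readout_order is required")
        Xf, was_frame = _as_frame(X)
        t = np.asarray(readout_order, float)
        V = Xf.to_numpy(float)
        if self.log_scale:
            V = np.log(V)
        fitted = self.intercepts_[None, :] + self.slopes_[None, :] * t[:, None]
        out = (V - fitted) - self.resid_medians_[None, :] + self.medians_[None, :]
        if self.log_scale:
            out = np.exp(out)
        if was_frame:
            return pd.DataFrame(out, index=Xf.index, columns=Xf.columns)
        return out

    def fit_transform(self, X, y=None, readout_order=None):
        return self.fit(X, readout_order=readout_order).transform(
            X, readout_order=readout_order)

    def log_dict(self) -> dict:
        """Per-protein fit log (slope, intercept, iterations)."""
        return {
            c: {"slope": float(self.slopes_[j]),
                "intercept": float(self.intercepts_[j]),
                "iterations": int(self.n_iter_[j])}
            for j, c in enumerate(self.columns_)
        }


class PlateNormalizer(BaseEstimator, TransformerMixin):
    """Equalize per-protein medians across plates by ratio scaling.

    For protein j on plate k, intensities are multiplied by
    ``global_median_j / plate_median_jk`` so that after correction every
    plate shares the protein's global median.  Plates with fewer than
    ``min_plate_size`` samples are left unadjusted (with a warning), as a
    plate median from so few samples is not a usable location estimate.
    """

    def __init__(self, min_plate_size: int = 3):
        self.min_plate_size = min_plate_size

    def fit(self, X, y=None, plate=None):
        if plate is None:
            raise ValueError("plate labels are required")
        Xf, _ = _as_frame(X)
        plate = np.asarray(plate)
        if len(plate) != len(Xf):
            raise ValueError("plate length does not match samples")
        V = Xf.to_numpy(float)
        self.global_medians_ = np.median(V, axis=0)
        self.plates_ = [p for p in pd.unique(plate)]
        self.factors_ = {}
        for pl in self.plates_:
            mask = plate == pl
            if mask.sum() < self.min_plate_size:
                warnings.warn(
                    f"plate {pl!r} has {int(mask.sum())} sample(s) "
                    f"(< {self.min_plate_size}); left unadjusted")
                self.factors_[pl] = np.ones(V.shape[1])
                continue
            pm = np.median(V[mask], axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                f = np.where(pm > 0, self.global_medians_ / pm, 1.0)
            self.factors_[pl] = f
        self.columns_ = list(Xf.columns)
        return self

    def transform(self, X, plate=None):
        if plate is None:
            raise ValueError("plate labels are required")
        Xf, was_frame = _as_frame(X)
        plate = np.asarray(plate)
        V = Xf.to_numpy(float).copy()
        for pl, f in self.factors_.items():
            mask = plate == pl
            V[mask] *= f[None, :]
        if was_frame:
            return pd.DataFrame(V, index=Xf.index, columns=Xf.columns)
        return V

    def fit_transform(self, X, y=None, plate=None):
        return self.fit(X, plate=plate).transform(X, plate=plate)

    def log_dict(self) -> dict:
        return {str(pl): [float(v) for v in f] for pl, f in self.factors_.items()}


def drift_normalize(matrix, readout_order, **kwargs):
    """One-shot readout-drift correction; see :class:`DriftNormalizer`."""
    return DriftNormalizer(**kwargs).fit_transform(matrix, readout_order=readout_order)


def plate_normalize(matrix, plate, **kwargs):
    """One-shot plate-median equalization; see :class:`PlateNormalizer`."""
    return PlateNormalizer(**kwargs).fit_transform(matrix, plate=plate)
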