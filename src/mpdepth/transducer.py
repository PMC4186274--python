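"""Log-space plane fit of the empirical motion/pursuit ratio.

Perceived depth matches d_mp follow a power law in the two rate signals,

    d_mp = k * f * dtheta**r / dalpha**e

which in natural-log space is a plane:

    ln(d_mp / f) = ln(k) + r * ln(dtheta) - e * ln(dalpha)

Ordinary least squares on [1, ln dtheta, ln dalpha] therefore recovers the
transducer exponents and scaling constant directly, together with the r^2 of
the plane. A variant refit first multiplies each depth match by a linear
stereo-distortion factor of viewing distance, quantifying how a hypothetical
failure of stereo depth constancy would move the exponents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .geometry import (
    AngleUnit,
    JohnstonScaling,
    TransducerModel,
    johnston_ratio,
)

__all__ = [
    "PlaneFitResult",
    "MotionPursuitPlaneFit",
    "fit_empirical_mpr",
    "johnston_adjust_and_refit",
    "predict_depth_surface",
]

#: Column order expected for the (n, 3) design: rates in deg/s, distance in cm.
DESIGN_COLUMNS = ["dtheta_deg_s", "dalpha_deg_s", "f_cm"]


@dataclass(frozen=True)
class PlaneFitResult:
    """OLS plane fit of ln(d_mp/f) on [1, ln dtheta, ln dalpha]."""

    intercept: float
    coef_log_dtheta: float
    coef_log_dalpha: float
    r_squared: float
    residuals: np.ndarray
    n_points: int
    n_excluded: int

    def to_model(self, angle_unit: AngleUnit = AngleUnit.DEGREE) -> TransducerModel:
        """Export as a transducer model: r = coef on ln dtheta,
        e = -coef on ln dalpha, k = exp(intercept)."""
        return TransducerModel(
            r=self.coef_log_dtheta,
            e=-self.coef_log_dalpha,
            k=math.exp(self.intercept),
            angle_unit=angle_unit,
        )


class MotionPursuitPlaneFit(BaseEstimator, RegressorMixin):
    """Estimator for the empirical motion/pursuit ratio.

    ``fit`` takes X of shape (n, 3) with columns (dtheta, dalpha, f) — rates
    in deg/s, viewing distance in cm — and y of depth matches d_mp in cm, and
    performs unweighted OLS in natural-log space (a weighted fit is available
    via ``weighted=True`` and ``sample_weight``). Non-positive depth matches
    carry no log-space information and are excluded (counted in
    ``n_excluded_``).

    Parameters
    ----------
    scaling : JohnstonScaling, optional
        If given, each d_mp is multiplied by ``johnston_ratio(f, scaling)``
        before fitting (stereo-distortion adjustment).
    weighted : bool
        Use weighted least squares with ``sample_weight``.

    Attributes
    ----------
    intercept_ : float       natural-log intercept, ln(k)
    coef_ : ndarray (2,)     coefficients on [ln dtheta, ln dalpha]
    r_, e_, k_ : float       exported transducer parameters
    r_squared_ : float       coefficient of determination of the plane
    n_points_, n_excluded_ : int
    """

    def __init__(self, scaling: JohnstonScaling | None = None, weighted: bool = False):
        self.scaling = scaling
        self.weighted = weighted

    def fit(self, X, y, sample_weight=None):
        if isinstance(X, pd.DataFrame):
            X = X[DESIGN_COLUMNS].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must be (n, 3): dtheta, dalpha, f")
        if X.shape[0] != y.size:
            raise ValueError("X and y lengths differ")
        if np.any(X <= 0):
            raise ValueError("rates and viewing distance must be positive")

        dtheta, dalpha, f = X.T
        if self.scaling is not None:
            y = y * johnston_ratio(f, self.scaling)

        keep = y > 0
        self.n_excluded_ = int((~keep).sum())
        dtheta, dalpha, f, y = dtheta[keep], dalpha[keep], f[keep], y[keep]
        if y.size < 4:
            raise ValueError("need at least 4 points with positive d_mp")
        if np.unique(dtheta).size < 2 or np.unique(dalpha).size < 2:
            raise ValueError("design must span >= 2 distinct dtheta and dalpha values")

        design = np.column_stack([np.ones_like(y), np.log(dtheta), np.log(dalpha)])
        if np.linalg.matrix_rank(design) < 3:
            raise ValueError(
                "rank-deficient design: ln(dtheta) and ln(dalpha) are collinear"
            )
        target = np.log(y / f)
        if self.weighted and sample_weight is not None:
            w = np.asarray(sample_weight, float)[keep]
            res = sm.WLS(target, design, weights=w).fit()
        else:
            res = sm.OLS(target, design).fit()

        self.intercept_ = float(res.params[0])
        self.coef_ = np.asarray(res.params[1:], dtype=float)
        self.r_ = float(res.params[1])
        self.e_ = float(-res.params[2])
        self.k_ = math.exp(self.intercept_)
        self.r_squared_ = float(res.rsquared)
        self.residuals_ = np.asarray(res.resid, dtype=float)
        self.n_points_ = int(y.size)
        return self

    def predict(self, X):
        """Predict d_mp (cm) at (dtheta, dalpha, f)."""
        check_is_fitted(self, "k_")
        if isinstance(X, pd.DataFrame):
            X = X[DESIGN_COLUMNS].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        dtheta, dalpha, f = X.T
        return self.k_ * f * dtheta**self.r_ / dalpha**self.e_

    def result_(self) -> PlaneFitResult:
        check_is_fitted(self, "k_")
        return PlaneFitResult(
            intercept=self.intercept_,
            coef_log_dtheta=self.r_,
            coef_log_dalpha=-self.e_,
            r_squared=self.r_squared_,
            residuals=self.residuals_,
            n_points=self.n_points_,
            n_excluded=self.n_excluded_,
        )


def _as_design(matches: pd.DataFrame):
    X = matches[DESIGN_COLUMNS]
    y = matches["d_mp_cm"].to_numpy(dtype=float)
    return X, y


def fit_empirical_mpr(matches: pd.DataFrame) -> tuple[PlaneFitResult, TransducerModel]:
    """Fit the empirical motion/pursuit ratio to a depth-match table.

    ``matches`` needs columns ``dtheta_deg_s``, ``dalpha_deg_s``, ``f_cm``
    and ``d_mp_cm``. Returns the plane fit and its transducer-model export.
    """
    est = MotionPursuitPlaneFit()
    X, y = _as_design(matches)
    est.fit(X, y)
    result = est.result_()
    return result, result.to_model()


def johnston_adjust_and_refit(
    matches: pd.DataFrame, js: JohnstonScaling | None = None
) -> tuple[PlaneFitResult, TransducerModel]:
    """Refit after scaling each d_mp by the stereo-distortion ratio at its f.

    With the default coefficients this inflates near-distance depth matches
    more than far ones, shifting the fitted exponents; a distance-independent
    scaling (b = 0) moves only k.
    """
    est = MotionPursuitPlaneFit(scaling=js or JohnstonScaling())
    X, y = _as_design(matches)
    est.fit(X, y)
    result = est.result_()
    return result, result.to_model()


def predict_depth_surface(
    model: TransducerModel, grid: pd.DataFrame
) -> pd.DataFrame:
    """Tabulate empirical vs geometric depth predictions over a stimulus grid.

    Adds columns ``d_empirical_cm`` (power-law prediction), ``d_geometric_cm``
    (motion/pursuit-ratio prediction (dtheta/dalpha)*f) and their ratio
    ``foreshortening`` (< 1 when perceived depth is compressed).
    """
    out = grid.copy()
    dtheta = out["dtheta_deg_s"].to_numpy(dtype=float)
    dalpha = out["dalpha_deg_s"].to_numpy(dtype=float)
    f = out["f_cm"].to_numpy(dtype=float)
    if np.any(dtheta <= 0) or np.any(dalpha <= 0):
        raise ValueError("grid rates must be positive")
    out["d_empirical_cm"] = model.k * f * dtheta**model.r / dalpha**model.e
    out["d_geometric_cm"] = dtheta / dalpha * f
    out["foreshortening"] = out["d_empirical_cm"] / out["d_geometric_cm"]
    return out
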