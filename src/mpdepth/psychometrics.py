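"""2IFC response aggregation and cumulative-normal psychometric fitting.

Observers judge on each trial whether a static stereo comparison stimulus has
greater depth than a motion parallax stimulus. Pooling trials per disparity
level gives a psychometric function: the proportion of "stereo deeper"
responses vs comparison disparity (arcmin). Its 50% point (PSE) is the
disparity whose stereo depth matches the perceived parallax depth; converting
the PSE through the distance-square law yields the depth-match estimate d_mp.
The spread sigma doubles as a depth-discrimination threshold after the same
conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .geometry import DisparityStimulus, StimulusCondition, disparity_to_depth
from .units import DEFAULT_INTEROCULAR_CM

__all__ = [
    "PsychometricFit",
    "DepthMatch",
    "PsychometricCumulativeNormal",
    "aggregate_trials",
    "fit_cumulative_normal",
    "pse_to_depth",
    "sigma_to_depth_threshold",
]

#: Columns that identify one psychometric function within a session table.
FUNCTION_KEYS = ["condition_id", "f_cm", "dtheta_deg_s", "dalpha_deg_s", "head_state"]


@dataclass(frozen=True)
class PsychometricFit:
    """PSE and spread of a cumulative-normal fit, in disparity units (arcmin)."""

    pse: float
    sigma: float
    n_levels: int
    converged: bool
    extrapolated: bool
    residual_sse: float


@dataclass(frozen=True)
class DepthMatch:
    """Perceived-depth estimate for one stimulus condition.

    d_mp is the depth (cm) of the disparity stimulus judged equal in depth to
    the parallax stimulus; se is its standard error across observers (NaN for
    a single fit).
    """

    d_mp: float
    f: float
    condition: StimulusCondition | None = None
    se: float = math.nan


class PsychometricCumulativeNormal(BaseEstimator):
    """Cumulative-normal psychometric function estimator.

    Fits p(delta) = Phi((delta - pse) / sigma) to per-level response
    proportions. The default criterion is unweighted nonlinear least squares
    on the proportions; ``method="probit"`` instead fits a binomial probit
    GLM on the response counts (pass trial counts as ``sample_weight``).

    Parameters
    ----------
    method : {"ls", "probit"}
        Fit criterion.

    Attributes
    ----------
    pse_ : float
        Point of subjective equality (50% point), arcmin.
    sigma_ : float
        Spread of the cumulative normal, arcmin.
    converged_ : bool
        False for degenerate data (flat proportions) or optimizer failure.
    extrapolated_ : bool
        True when the PSE lies outside the fitted disparity range.
    residual_sse_ : float
        Sum of squared residuals of the proportions.
    n_levels_ : int
        Number of disparity levels fitted.
    """

    def __init__(self, method: str = "ls"):
        self.method = method

    def fit(self, X, y, sample_weight=None):
        """Fit to disparity levels X (n,) or (n, 1) and proportions y in [0, 1]."""
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if x.size < 3:
            raise ValueError("need at least 3 disparity levels to fit")
        if np.any((y < 0) | (y > 1)):
            raise ValueError("proportions must lie in [0, 1]")
        if self.method not in ("ls", "probit"):
            raise ValueError(f"unknown method {self.method!r}")

        self.n_levels_ = x.size
        self.x_min_, self.x_max_ = float(x.min()), float(x.max())

        if np.ptp(y) == 0:  # flat data: no information about pse or sigma
            self.pse_ = math.nan
            self.sigma_ = math.nan
            self.converged_ = False
            self.extrapolated_ = True
            self.residual_sse_ = math.nan
            return self

        if self.method == "probit":
            self._fit_probit(x, y, sample_weight)
        else:
            self._fit_ls(x, y)

        self.extrapolated_ = not (self.x_min_ <= self.pse_ <= self.x_max_)
        resid = y - norm.cdf((x - self.pse_) / self.sigma_)
        self.residual_sse_ = float(resid @ resid)
        return self

    def _initial_guess(self, x, y):
        order = np.argsort(x)
        xs, ys = x[order], y[order]
        # first crossing of 0.5, linearly interpolated; fall back to midpoint
        cross = np.nonzero(np.diff(np.sign(ys - 0.5)) != 0)[0]
        if cross.size:
            j = cross[0]
            if ys[j + 1] != ys[j]:
                pse0 = xs[j] + (0.5 - ys[j]) * (xs[j + 1] - xs[j]) / (ys[j + 1] - ys[j])
            else:
                pse0 = 0.5 * (xs[j] + xs[j + 1])
        else:
            pse0 = xs[np.argmin(np.abs(ys - 0.5))]
        sigma0 = max(np.ptp(xs) / 4.0, 1e-3)
        return float(pse0), float(sigma0)

    def _fit_ls(self, x, y):
        p0 = self._initial_guess(x, y)
        span = np.ptp(x)
        try:
            popt, _ = curve_fit(
                lambda d, pse, sigma: norm.cdf((d - pse) / sigma),
                x,
                y,
                p0=p0,
                bounds=([x.min() - 10 * span, 1e-6], [x.max() + 10 * span, 50 * span]),
                maxfev=5000,
            )
            self.pse_, self.sigma_ = float(popt[0]), float(popt[1])
            self.converged_ = True
        except RuntimeError:
            self.pse_, self.sigma_ = p0
            self.converged_ = False

    def _fit_probit(self, x, y, sample_weight):
        import statsmodels.api as sm

        w = np.ones_like(x) if sample_weight is None else np.asarray(sample_weight, float)
        endog = np.column_stack([y * w, (1 - y) * w])
        exog = sm.add_constant(x)
        model = sm.GLM(endog, exog, family=sm.families.Binomial(sm.families.links.Probit()))
        try:
            res = model.fit()
            b0, b1 = res.params
            if b1 <= 0:
                raise ValueError("non-increasing psychometric function")
            self.pse_ = float(-b0 / b1)
            self.sigma_ = float(1.0 / b1)
            self.converged_ = True
        except Exception:
            self.pse_, self.sigma_ = self._initial_guess(x, y)
            self.converged_ = False

    def predict(self, X):
        """Predicted proportion of "stereo deeper" responses at disparities X."""
        check_is_fitted(self, "pse_")
        x = np.asarray(X, dtype=float).reshape(-1)
        return norm.cdf((x - self.pse_) / self.sigma_)

    def to_fit(self) -> PsychometricFit:
        """Export the fitted parameters as an immutable record."""
        check_is_fitted(self, "pse_")
        return PsychometricFit(
            pse=self.pse_,
            sigma=self.sigma_,
            n_levels=self.n_levels_,
            converged=self.converged_,
            extrapolated=self.extrapolated_,
            residual_sse=self.residual_sse_,
        )


def aggregate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Pool trials into per-level response proportions.

    Groups by psychometric-function key (condition, stimulus rates) and
    disparity level, pooling blocks and left/right directions. Returns a
    table with columns ``n_trials``, ``n_stereo_deeper`` and ``proportion``.

    Raises if one condition label mixes viewing distances, which would make
    the disparity-to-depth conversion ambiguous.
    """
    if trials.empty:
        raise ValueError("trial table is empty")
    per_cond_f = trials.groupby("condition_id")["f_cm"].nunique()
    bad = per_cond_f[per_cond_f > 1]
    if not bad.empty:
        raise ValueError(
            f"condition(s) {list(bad.index)} mix multiple viewing distances"
        )
    grouped = (
        trials.groupby(FUNCTION_KEYS + ["disparity_arcmin"], as_index=False)
        .agg(
            n_trials=("response_stereo_deeper", "size"),
            n_stereo_deeper=("response_stereo_deeper", "sum"),
        )
    )
    grouped["proportion"] = grouped["n_stereo_deeper"] / grouped["n_trials"]
    return grouped


def fit_cumulative_normal(table: pd.DataFrame, method: str = "ls") -> PsychometricFit:
    """Fit one psychometric function from an aggregated response table.

    ``table`` must hold one function: columns ``disparity_arcmin`` and
    ``proportion`` (and optionally ``n_trials``, used as weights for the
    probit method).
    """
    est = PsychometricCumulativeNormal(method=method)
    weights = table["n_trials"].to_numpy() if "n_trials" in table else None
    est.fit(table["disparity_arcmin"], table["proportion"], sample_weight=weights)
    return est.to_fit()


def pse_to_depth(
    fit: PsychometricFit,
    f: float,
    i: float = DEFAULT_INTEROCULAR_CM,
    condition: StimulusCondition | None = None,
) -> DepthMatch:
    """Convert a PSE (arcmin) to a perceived-depth match d_mp (cm)."""
    if not fit.converged:
        raise ValueError("cannot convert an unconverged psychometric fit to depth")
    d = disparity_to_depth(DisparityStimulus(delta=fit.pse, f=f, i=i))
    return DepthMatch(d_mp=d, f=f, condition=condition)


def sigma_to_depth_threshold(
    fit: PsychometricFit, f: float, i: float = DEFAULT_INTEROCULAR_CM
) -> float:
    """Depth-discrimination threshold (cm) equivalent to the fitted sigma."""
    if not fit.converged:
        raise ValueError("cannot convert an unconverged psychometric fit")
    return disparity_to_depth(DisparityStimulus(delta=fit.sigma, f=f, i=i))
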