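"""Calibration models linking optical rotation to concentration.

Three routes are provided: direct inversion through the specific rotation
(``c = theta / ([theta] * l)``), a piecewise quadratic regression with a
rotation threshold ``theta_t`` separating two independently fitted
segments (glucose), and a single ordinary least-squares line (naproxen).
A deterministic studentized-residual rule removes a bounded number of
outliers before fitting.

The regressors are scikit-learn estimators; the module-level functions
``fit_piecewise_quadratic`` / ``fit_linear`` / ``predict_concentration``
are thin wrappers returning the plain dataclass models used for
serialization.
"""
from __future__ import annotations

import math
import warnings

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .types import LinearModel, PiecewiseQuadModel, SpecificRotationParams

#: Per-polarization rotation thresholds (radians) for serum-based samples;
#: each sits near the 200 mg/dl rotation magnitude for that incidence.
SERUM_THETA_T = {"V": 0.88, "P": 0.98, "R": 0.822}
#: Same for aqueous glucose samples.
AQUEOUS_THETA_T = {"V": 0.88, "P": 1.025, "R": 0.97}


class NegativePredictionWarning(UserWarning):
    """Raised when a negative predicted concentration was floored at zero."""


def concentration_from_specific_rotation(
    theta: float,
    params: SpecificRotationParams,
    path_length: float,
) -> float:
    """Invert ``theta = [theta] * c * l`` for the concentration.

    Units must be declared consistently by the caller (e.g. specific
    rotation in rad/(m * mg/dl) with ``path_length`` in meters gives
    mg/dl).
    """
    if params.specific_rotation == 0:
        raise ValueError("specific_rotation must be nonzero to invert")
    if path_length <= 0:
        raise ValueError("path_length must be positive")
    return float(theta) / (params.specific_rotation * path_length)


def remove_outliers(
    theta,
    concentration,
    max_removed: int = 3,
    threshold: float = 2.5,
):
    """Iteratively drop gross outliers from (theta, concentration) pairs.

    At each step a provisional quadratic is fitted by OLS and the point
    with the largest internally studentized residual is removed if that
    residual exceeds ``threshold`` in magnitude, up to ``max_removed``
    removals.  Returns ``(theta_kept, conc_kept, removed_indices)`` with
    removed indices referring to the original ordering.  Deterministic.
    """
    theta = np.asarray(theta, dtype=float)
    concentration = np.asarray(concentration, dtype=float)
    if theta.shape != concentration.shape or theta.ndim != 1:
        raise ValueError("theta and concentration must be equal-length 1-D arrays")
    if theta.size < 6:
        raise ValueError("need at least 6 pairs for outlier screening")
    if max_removed < 0:
        raise ValueError("max_removed must be nonnegative")

    keep = np.arange(theta.size)
    removed: list[int] = []
    for _ in range(max_removed):
        t, c = theta[keep], concentration[keep]
        if t.size < 5:  # need residual degrees of freedom beyond the 3 parameters
            break
        design = sm.add_constant(np.column_stack([t, t**2]))
        fit = sm.OLS(c, design).fit()
        if fit.ssr <= 1e-24 * max(1.0, float(np.sum(c**2))):
            break  # essentially exact fit: nothing to remove
        resid = fit.get_influence().resid_studentized_internal
        worst = int(np.argmax(np.abs(resid)))
        if not np.isfinite(resid[worst]) or abs(resid[worst]) <= threshold:
            break
        removed.append(int(keep[worst]))
        keep = np.delete(keep, worst)
    return theta[keep], concentration[keep], sorted(removed)


class PiecewiseQuadraticRegressor(RegressorMixin, BaseEstimator):
    """Two free quadratics in rotation, split at a threshold.

    Parameters
    ----------
    theta_t : float or "auto"
        Rotation threshold (radians).  ``"auto"`` selects the threshold
        from the grid of observed rotation values, minimizing the total
        residual sum of squares, with ties broken toward the smaller
        threshold.
    min_segment : int
        Minimum number of points required on each side of the threshold.

    Attributes
    ----------
    coef_lower_, coef_upper_ : ndarray of shape (3,)
        Quadratic coefficients ``[a, b, k]`` (highest power first) for the
        ``theta <= theta_t`` and ``theta > theta_t`` segments.
    theta_t_ : float
        The threshold actually used.
    """

    def __init__(self, theta_t="auto", min_segment: int = 3):
        self.theta_t = theta_t
        self.min_segment = min_segment

    @staticmethod
    def _fit_segments(theta, conc, theta_t, min_segment):
        lower = theta <= theta_t
        upper = ~lower
        if np.count_nonzero(lower) < min_segment:
            raise ValueError(
                f"lower segment (theta <= {theta_t:g}) has fewer than "
                f"{min_segment} points"
            )
        if np.count_nonzero(upper) < min_segment:
            raise ValueError(
                f"upper segment (theta > {theta_t:g}) has fewer than "
                f"{min_segment} points"
            )
        coef_lo = np.polyfit(theta[lower], conc[lower], 2)
        coef_hi = np.polyfit(theta[upper], conc[upper], 2)
        ssr = float(
            np.sum((np.polyval(coef_lo, theta[lower]) - conc[lower]) ** 2)
            + np.sum((np.polyval(coef_hi, theta[upper]) - conc[upper]) ** 2)
        )
        return coef_lo, coef_hi, ssr

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[1] != 1:
            raise ValueError("X must be a single column of rotation values")
        theta = X[:, 0]
        conc = np.asarray(y, dtype=float)
        if theta.shape != conc.shape:
            raise ValueError("X and y lengths differ")
        if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(conc))):
            raise ValueError("non-finite training data")

        if self.theta_t == "auto":
            candidates = np.unique(theta)
            best = None
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", np.exceptions.RankWarning)
                for cand in candidates:
                    try:
                        coef_lo, coef_hi, ssr = self._fit_segments(
                            theta, conc, cand, self.min_segment
                        )
                    except ValueError:
                        continue
                    # strict < keeps the smallest threshold on ties
                    if best is None or ssr < best[0] - 1e-12 * max(1.0, best[0]):
                        best = (ssr, cand, coef_lo, coef_hi)
            if best is None:
                raise ValueError(
                    "no threshold candidate leaves at least "
                    f"{self.min_segment} points on each side"
                )
            _, theta_t, coef_lo, coef_hi = best
        else:
            theta_t = float(self.theta_t)
            coef_lo, coef_hi, _ = self._fit_segments(
                theta, conc, theta_t, self.min_segment
            )
        self.theta_t_ = float(theta_t)
        self.coef_lower_ = coef_lo
        self.coef_upper_ = coef_hi
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "theta_t_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        theta = X[:, 0]
        if not np.all(np.isfinite(theta)):
            raise ValueError("non-finite rotation values")
        lower = theta <= self.theta_t_
        out = np.empty_like(theta)
        out[lower] = np.polyval(self.coef_lower_, theta[lower])
        out[~lower] = np.polyval(self.coef_upper_, theta[~lower])
        return out

    def to_model(self, units_out: str = "mg/dl") -> PiecewiseQuadModel:
        """Export the fitted coefficients as a serializable dataclass."""
        check_is_fitted(self, "theta_t_")
        a1, b1, k1 = (float(v) for v in self.coef_lower_)
        a2, b2, k2 = (float(v) for v in self.coef_upper_)
        return PiecewiseQuadModel(
            a1=a1, b1=b1, k1=k1, a2=a2, b2=b2, k2=k2,
            theta_t=self.theta_t_, units_out=units_out,
        )


def fit_piecewise_quadratic(theta, concentration, theta_t="auto") -> PiecewiseQuadModel:
    """OLS fit of the two-segment quadratic calibration model.

    The segments are fitted independently (no continuity constraint at the
    threshold).  ``theta_t`` may be a fixed threshold in radians or
    ``"auto"``.
    """
    est = PiecewiseQuadraticRegressor(theta_t=theta_t)
    est.fit(np.asarray(theta, dtype=float), np.asarray(concentration, dtype=float))
    return est.to_model()


def predict_concentration(model: PiecewiseQuadModel, theta):
    """Predicted concentration(s) from the piecewise quadratic model.

    The lower branch is inclusive (``theta <= theta_t``).  Negative
    predictions are floored at zero with a warning.  Accepts a scalar or
    an array; returns the matching shape.
    """
    arr = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("theta must be finite")
    scalar = arr.ndim == 0
    flat = np.atleast_1d(arr)
    lower = flat <= model.theta_t
    out = np.empty_like(flat)
    out[lower] = model.a1 * flat[lower] ** 2 + model.b1 * flat[lower] + model.k1
    out[~lower] = model.a2 * flat[~lower] ** 2 + model.b2 * flat[~lower] + model.k2
    if np.any(out < 0):
        warnings.warn(
            "negative predicted concentration floored at 0", NegativePredictionWarning
        )
        out = np.clip(out, 0.0, None)
    return float(out[0]) if scalar else out


def fit_linear(theta, concentration) -> LinearModel:
    """Single-line OLS calibration (used for naproxen)."""
    theta = np.asarray(theta, dtype=float)
    concentration = np.asarray(concentration, dtype=float)
    if theta.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.ptp(theta) == 0:
        raise ValueError("all rotation values identical; slope undefined")
    if np.ptp(concentration) == 0:
        # OLS slope is exactly 0 and no variance is explained
        return LinearModel(slope=0.0, intercept=float(concentration[0]), r_squared=0.0)
    result = stats.linregress(theta, concentration)
    return LinearModel(
        slope=float(result.slope),
        intercept=float(result.intercept),
        r_squared=float(result.rvalue) ** 2,
    )


def predict_linear(model: LinearModel, theta):
    """Concentration(s) from the linear calibration model."""
    arr = np.asarray(theta, dtype=float)
    out = model.slope * arr + model.intercept
    return float(out) if arr.ndim == 0 else out
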