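"""Nonlinear least-squares fitting of the Weibull vulnerability curve.

The central object is :class:`WeibullVulnerabilityCurve`, a scikit-learn
style regressor: ``X`` is a single column of xylem tensions (MPa, positive
magnitudes) and ``y`` the observed loss-of-conductivity fractions.  Fitting
minimises the unweighted sum of squared LC residuals starting from a
linearised (Weibull-plot) initial guess; the fitted scale and shape are
exposed as ``a_`` and ``b_`` and the key points through
:meth:`~WeibullVulnerabilityCurve.key_points`.

Module-level functions (``fit_weibull``, ``bootstrap_ci``, ``initial_guess``)
are thin wrappers over the estimator operating on observation tables
(DataFrames with columns ``sample_id``, ``psi_mpa``, ``lc``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .exceptions import DomainError, FitError, ValidationError
from .weibull import (
    KeyPointSet,
    TraditionalPoints,
    WeibullParams,
    dm_key_points,
    tm_points,
    weibull_lc,
)

__all__ = [
    "FitResult",
    "WeibullVulnerabilityCurve",
    "initial_guess",
    "fit_weibull",
    "bootstrap_ci",
    "fit_per_sample",
]

logger = logging.getLogger(__name__)


@dataclass
class FitResult:
    """Outcome of a vulnerability-curve fit.

    ``residuals`` are observed minus fitted LC, ``r_squared`` is
    1 - SS_res/SS_tot on LC, and ``ci_a``/``ci_b`` are percentile bootstrap
    intervals when a bootstrap was run (with ``seed`` recording how).
    """

    params: WeibullParams
    r_squared: float
    residuals: np.ndarray = field(repr=False)
    n_obs: int
    ci_a: Optional[tuple[float, float]] = None
    ci_b: Optional[tuple[float, float]] = None
    seed: Optional[int] = None


def _extract(observations) -> tuple[np.ndarray, np.ndarray]:
    """Pull (psi, lc) arrays out of a table or a (psi, lc) pair."""
    if isinstance(observations, pd.DataFrame):
        missing = {"psi_mpa", "lc"} - set(observations.columns)
        if missing:
            raise ValidationError(f"observation table missing columns: {sorted(missing)}")
        return (
            observations["psi_mpa"].to_numpy(dtype=float),
            observations["lc"].to_numpy(dtype=float),
        )
    psi, lc = observations
    return np.asarray(psi, dtype=float), np.asarray(lc, dtype=float)


def initial_guess(observations) -> WeibullParams:
    """Starting parameters from a Weibull-plot linearisation.

    Ordinary least squares of log(-log(1 - lc)) on log(psi): the slope is
    the shape ``b`` and the intercept ``-b log a``.  Points with lc in
    {0, 1} or psi = 0 are excluded (log singularities); at least two usable
    points with distinct tensions are required.
    """
    psi, lc = _extract(observations)
    usable = (lc > 0) & (lc < 1) & (psi > 0)
    psi_u, lc_u = psi[usable], lc[usable]
    if psi_u.size < 2:
        raise DomainError(
            "initial guess needs >= 2 observations with 0 < lc < 1 and psi > 0; "
            f"got {psi_u.size}"
        )
    if np.unique(psi_u).size < 2:
        raise DomainError("initial guess needs >= 2 distinct psi values")
    x = np.log(psi_u)
    z = np.log(-np.log1p(-lc_u))
    slope, intercept = np.polyfit(x, z, 1)
    if slope <= 0:
        # Non-increasing cloud; fall back to a mild shape with a matched scale.
        slope = 1.0
        intercept = -np.median(x)
    b = float(slope)
    a = float(math.exp(-intercept / b))
    return WeibullParams(a=a, b=b)


class WeibullVulnerabilityCurve(RegressorMixin, BaseEstimator):
    """Weibull vulnerability curve fitted by nonlinear least squares.

    Parameters
    ----------
    max_iter : int
        Maximum number of optimiser iterations.
    tol : float
        Relative parameter/cost tolerance passed to the optimiser.  The
        problem is a smooth two-parameter fit, so tight tolerances are cheap.
    n_boot : int
        If > 0, run a case-resampling bootstrap of this size after the fit
        and store percentile confidence intervals in ``ci_a_``/``ci_b_``.
    ci_level : float
        Bootstrap interval coverage level (default 0.95).
    random_state : int or None
        Seed for the bootstrap resampling; required for reproducibility.

    Attributes
    ----------
    a_, b_ : float
        Fitted scale (MPa tension) and shape.
    params_ : WeibullParams
    r_squared_ : float
    residuals_ : ndarray  (observed minus fitted LC)
    n_obs_ : int
    ci_a_, ci_b_ : tuple of (lower, upper), set when ``n_boot > 0``
    n_boot_redrawn_ : int, degenerate resamples redrawn during the bootstrap

    Examples
    --------
    >>> import numpy as np
    >>> from hvcurve.fitting import WeibullVulnerabilityCurve
    >>> from hvcurve.weibull import WeibullParams, weibull_lc
    >>> psi = np.linspace(0.2, 6.0, 30)
    >>> lc = weibull_lc(WeibullParams(2.23, 2.50), psi)
    >>> model = WeibullVulnerabilityCurve().fit(psi[:, None], lc)
    >>> round(model.a_, 3), round(model.b_, 3)
    (2.23, 2.5)
    """

    def __init__(
        self,
        *,
        max_iter: int = 200,
        tol: float = 1e-10,
        n_boot: int = 0,
        ci_level: float = 0.95,
        random_state: Optional[int] = None,
    ):
        self.max_iter = max_iter
        self.tol = tol
        self.n_boot = n_boot
        self.ci_level = ci_level
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X, y):
        """Fit to tensions ``X`` (n_samples, 1; MPa) and LC fractions ``y``."""
        X, y = check_X_y(X, y, y_numeric=True, ensure_min_samples=3)
        if X.shape[1] != 1:
            raise ValidationError(
                f"X must be a single column of tensions (MPa); got {X.shape[1]} columns"
            )
        psi = X[:, 0]
        if np.any(psi < 0):
            raise DomainError("tensions must be >= 0 (positive magnitudes, MPa)")
        if np.any((y < 0) | (y > 1)):
            raise DomainError("loss-of-conductivity values must lie in [0, 1]")
        if np.unique(psi).size < 2:
            raise ValidationError("need at least 2 distinct psi values to fit")
        if np.all(y == 0):
            raise DomainError("curve degenerate: all loss-of-conductivity values are zero")

        guess = initial_guess((psi, y))
        a_est, b_est = self._solve(psi, y, guess)

        self.a_ = a_est
        self.b_ = b_est
        self.params_ = WeibullParams(a=a_est, b=b_est)
        fitted = weibull_lc(self.params_, psi)
        self.residuals_ = y - fitted
        ss_res = float(np.sum(self.residuals_**2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        self.n_obs_ = int(y.size)
        self.n_features_in_ = 1

        if self.n_boot:
            self._bootstrap(psi, y)
        return self

    def _solve(self, psi, lc, guess: WeibullParams) -> tuple[float, float]:
        def resid(theta):
            a, b = theta
            return -np.expm1(-np.power(psi / a, b)) - lc

        def jac(theta):
            a, b = theta
            with np.errstate(divide="ignore", invalid="ignore"):
                u = psi / a
                s = np.power(u, b)
                e = np.exp(-s)
                d_a = -(b / a) * s * e
                d_b = np.where(psi > 0, e * s * np.log(np.where(psi > 0, u, 1.0)), 0.0)
            return np.column_stack([d_a, d_b])

        res = least_squares(
            resid,
            x0=[guess.a, guess.b],
            jac=jac,
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            xtol=self.tol,
            ftol=self.tol,
            gtol=self.tol,
            max_nfev=self.max_iter,
        )
        if not res.success:
            raise FitError(
                f"fit did not converge within {self.max_iter} iterations "
                f"(optimizer status {res.status})",
                last_params=WeibullParams(a=float(res.x[0]), b=float(res.x[1])),
            )
        return float(res.x[0]), float(res.x[1])

    def _bootstrap(self, psi, lc):
        if self.n_boot < 100:
            raise ValidationError(f"bootstrap needs n_boot >= 100, got {self.n_boot}")
        rng = np.random.default_rng(self.random_state)
        n = psi.size
        a_rep = np.empty(self.n_boot)
        b_rep = np.empty(self.n_boot)
        redrawn = 0
        for k in range(self.n_boot):
            for _attempt in range(1000):
                idx = rng.integers(0, n, size=n)
                p, l = psi[idx], lc[idx]
                usable = (l > 0) & (l < 1) & (p > 0)
                if p.size >= 3 and np.unique(p).size >= 2 and usable.sum() >= 2 and not np.all(l == 0):
                    break
                redrawn += 1
            else:  # pragma: no cover - pathological data
                raise FitError("could not draw a non-degenerate bootstrap resample")
            try:
                a_rep[k], b_rep[k] = self._solve(p, l, initial_guess((p, l)))
            except (FitError, DomainError):
                a_rep[k], b_rep[k] = self._solve(p, l, self.params_)
        if redrawn:
            logger.info("bootstrap redrew %d degenerate resamples", redrawn)
        alpha = (1.0 - self.ci_level) / 2.0
        self.ci_a_ = tuple(np.quantile(a_rep, [alpha, 1 - alpha]))
        self.ci_b_ = tuple(np.quantile(b_rep, [alpha, 1 - alpha]))
        self.n_boot_redrawn_ = redrawn

    # --------------------------------------------------------------- output
    def predict(self, X):
        """Predicted loss of conductivity at tensions ``X`` (n_samples, 1)."""
        check_is_fitted(self, "params_")
        X = check_array(X)
        return weibull_lc(self.params_, X[:, 0])

    def key_points(self) -> KeyPointSet:
        """Differential-method key points of the fitted curve."""
        check_is_fitted(self, "params_")
        return dm_key_points(self.params_)

    def traditional_points(self) -> TraditionalPoints:
        """Traditional-method (12/50/88% loss) points of the fitted curve."""
        check_is_fitted(self, "params_")
        return tm_points(self.params_)

    def result(self) -> FitResult:
        check_is_fitted(self, "params_")
        return FitResult(
            params=self.params_,
            r_squared=self.r_squared_,
            residuals=self.residuals_,
            n_obs=self.n_obs_,
            ci_a=getattr(self, "ci_a_", None),
            ci_b=getattr(self, "ci_b_", None),
            seed=self.random_state,
        )


def fit_weibull(
    observations,
    *,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> FitResult:
    """Fit the Weibull curve to a pooled observation table.

    ``observations`` is a DataFrame with columns ``psi_mpa`` and ``lc``
    (``sample_id`` is carried but ignored: the default is a pooled fit
    across samples) or a ``(psi, lc)`` array pair.
    """
    psi, lc = _extract(observations)
    est = WeibullVulnerabilityCurve(max_iter=max_iter, tol=tol)
    est.fit(psi[:, None], lc)
    return est.result()


def bootstrap_ci(
    observations,
    n_boot: int = 1000,
    seed: Optional[int] = None,
    level: float = 0.95,
) -> FitResult:
    """Fit plus case-resampling percentile bootstrap intervals for (a, b).

    Case resampling (rows, not residuals) is used because the LC noise model
    is unknown and heteroscedastic near lc in {0, 1}.  Reproducible under a
    fixed ``seed``.
    """
    psi, lc = _extract(observations)
    est = WeibullVulnerabilityCurve(n_boot=n_boot, ci_level=level, random_state=seed)
    est.fit(psi[:, None], lc)
    return est.result()


def fit_per_sample(observations: pd.DataFrame) -> tuple[dict[str, FitResult], dict]:
    """Grouped alternative to the pooled fit: one curve per ``sample_id``.

    Returns per-sample fit results and a summary with the mean and standard
    error of the scale and shape across samples.
    """
    if "sample_id" not in observations.columns:
        raise ValidationError("per-sample fitting requires a sample_id column")
    results: dict[str, FitResult] = {}
    for sid, grp in observations.groupby("sample_id", sort=True):
        results[str(sid)] = fit_weibull(grp)
    a_vals = np.array([r.params.a for r in results.values()])
    b_vals = np.array([r.params.b for r in results.values()])
    n = len(results)
    summary = {
        "n_samples": n,
        "a_mean": float(a_vals.mean()),
        "a_se": float(a_vals.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
        "b_mean": float(b_vals.mean()),
        "b_se": float(b_vals.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
    }
    return results, summary
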