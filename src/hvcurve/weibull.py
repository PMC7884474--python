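"""Weibull model of the hydraulic vulnerability curve and its key points.

A hydraulic vulnerability curve (HVC) relates xylem tension to the fractional
loss of hydraulic conductivity (LC) as embolism spreads.  This module fixes
the functional form to the Weibull cumulative distribution function

    LC(psi) = 1 - exp[-(psi / a)^b]

with scale ``a`` (MPa) and shape ``b`` (dimensionless), and extracts the
three key hydraulic points two ways:

* **Differential method (DM)** — closed-form roots of the curve's second and
  third derivatives: the air-entry point ``psi_e`` (lower third-derivative
  root, cavitation onset), the fastest-drop point ``psi_m`` (inflection,
  second-derivative root), and the lethal point ``psi_l`` (upper
  third-derivative root, the point of no return).
* **Traditional method (TM)** — the tensions at 12%, 50% and 88% loss,
  i.e. quantiles of the fitted curve.

Sign convention (stated once, applies package-wide): water potentials are
stored as **positive tension magnitudes in MPa**.  Negative inputs are
rejected, never silently negated.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.optimize import brentq

from .exceptions import DomainError

__all__ = [
    "WeibullParams",
    "KeyPointSet",
    "TraditionalPoints",
    "PeriodLabel",
    "weibull_lc",
    "weibull_derivatives",
    "dm_key_points",
    "tm_points",
    "lc_quantile",
    "numeric_key_points",
    "classify_period",
]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class WeibullParams:
    """Fitted Weibull parameters: scale ``a`` (MPa tension) and shape ``b``.

    Both must be strictly positive.  DM key points additionally require
    ``b > 1`` (interior inflection exists) and the air-entry point requires
    ``b > 2`` (the lower third-derivative root is positive only then).
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and self.a > 0):
            raise DomainError(f"scale parameter a must be finite and > 0, got {self.a}")
        if not (np.isfinite(self.b) and self.b > 0):
            raise DomainError(f"shape parameter b must be finite and > 0, got {self.b}")


@dataclass(frozen=True)
class KeyPointSet:
    """Differential-method key points and their loss-of-conductivity values.

    ``psi_e``/``lc_e`` are ``None`` when the shape parameter satisfies
    1 < b <= 2, where the curve has no positive lower turning point.
    """

    psi_m: float
    psi_l: float
    lc_m: float
    lc_l: float
    psi_e: Optional[float] = None
    lc_e: Optional[float] = None

    @property
    def complete(self) -> bool:
        """True when the air-entry point exists (shape b > 2)."""
        return self.psi_e is not None


@dataclass(frozen=True)
class TraditionalPoints:
    """Traditional-method points: tensions at 12%, 50% and 88% loss."""

    psi_12: float
    psi_50: float
    psi_88: float


class PeriodLabel(enum.Enum):
    """Four-period partition of the vulnerability curve by the DM key points."""

    STATIONARY = "stationary"
    ACCELERATED_DECLINE = "accelerated_decline"
    DECELERATED_DECLINE = "decelerated_decline"
    PLATFORM = "platform"


def _as_tension(psi: ArrayLike, *, strict: bool = False) -> np.ndarray:
    arr = np.asarray(psi, dtype=float)
    if strict:
        if np.any(arr <= 0):
            raise DomainError(
                "psi must be > 0 (positive tension magnitude, MPa); "
                f"got {arr[arr <= 0][:3]!r}"
            )
    elif np.any(arr < 0):
        raise DomainError(
            "psi must be >= 0; water potentials are handled as positive "
            f"tension magnitudes (MPa), got {arr[arr < 0][:3]!r}"
        )
    return arr


def weibull_lc(params: WeibullParams, psi: ArrayLike) -> ArrayLike:
    """Loss of conductivity at tension ``psi`` (MPa), in [0, 1).

    Evaluates ``1 - exp[-(psi/a)^b]``.  Accepts scalars or arrays;
    ``psi`` must be non-negative.
    """
    arr = _as_tension(psi)
    out = -np.expm1(-np.power(arr / params.a, params.b))
    return float(out) if np.isscalar(psi) or np.ndim(psi) == 0 else out


def weibull_derivatives(
    params: WeibullParams, psi: ArrayLike
) -> tuple[ArrayLike, ArrayLike, ArrayLike]:
    """First three analytic derivatives of the vulnerability curve at ``psi``.

    The first derivative is the slope (rate of embolism spread per MPa),
    the second its rate of change, and the third locates the curve's
    turning points.  Requires ``psi > 0``: the closed forms carry
    ``psi^(b-k)`` factors that are singular at the origin for small ``b``.
    """
    a, b = params.a, params.b
    arr = _as_tension(psi, strict=True)
    u = arr / a
    ub = np.power(u, b)
    e = np.exp(-ub)
    d1 = (b / a) * e * np.power(u, b - 1)
    d2 = (b / a**2) * e * np.power(u, b - 2) * (b - 1 - b * ub)
    d3 = (
        (b / a**3)
        * e
        * np.power(u, b - 3)
        * (b**2 * ub**2 - 3 * b * (b - 1) * ub + (b - 1) * (b - 2))
    )
    if np.isscalar(psi) or np.ndim(psi) == 0:
        return float(d1), float(d2), float(d3)
    return d1, d2, d3


def dm_key_points(params: WeibullParams) -> KeyPointSet:
    """Differential-method key points, closed form.

    The inflection (fastest-drop) point is

        psi_m = a * ((b-1)/b)^(1/b)

    and the turning points are ``a * u^(1/b)`` with

        u = [3(b-1) -/+ sqrt((b-1)(5b-1))] / (2b)

    (lower sign: air entry ``psi_e``; upper sign: lethal point ``psi_l``).
    The lower root is positive only for ``b > 2``; for 1 < b <= 2 the
    air-entry point is reported absent (``None``).  ``b <= 1`` has no
    interior inflection point at all and is a domain error.
    """
    a, b = params.a, params.b
    if b <= 1:
        raise DomainError(
            f"DM key points require shape b > 1 (no interior inflection point); got b={b}"
        )
    psi_m = a * ((b - 1) / b) ** (1.0 / b)
    disc = math.sqrt((b - 1) * (5 * b - 1))
    u_hi = (3 * (b - 1) + disc) / (2 * b)
    u_lo = (3 * (b - 1) - disc) / (2 * b)
    psi_l = a * u_hi ** (1.0 / b)
    lc_m = weibull_lc(params, psi_m)
    lc_l = weibull_lc(params, psi_l)
    if u_lo <= 0:  # 1 < b <= 2: no positive lower turning point
        return KeyPointSet(psi_m=psi_m, psi_l=psi_l, lc_m=lc_m, lc_l=lc_l)
    psi_e = a * u_lo ** (1.0 / b)
    return KeyPointSet(
        psi_m=psi_m,
        psi_l=psi_l,
        lc_m=lc_m,
        lc_l=lc_l,
        psi_e=psi_e,
        lc_e=weibull_lc(params, psi_e),
    )


def lc_quantile(params: WeibullParams, p: float) -> float:
    """Tension (MPa) producing loss fraction ``p``: ``a * (-ln(1-p))^(1/b)``."""
    if not 0 < p < 1:
        raise DomainError(f"quantile level p must lie in (0, 1), got {p}")
    return params.a * (-math.log1p(-p)) ** (1.0 / params.b)


def tm_points(params: WeibullParams) -> TraditionalPoints:
    """Traditional-method points: quantiles of the curve at 12%, 50%, 88% loss."""
    return TraditionalPoints(
        psi_12=lc_quantile(params, 0.12),
        psi_50=lc_quantile(params, 0.50),
        psi_88=lc_quantile(params, 0.88),
    )


def numeric_key_points(params: WeibullParams) -> KeyPointSet:
    """Key points by bracketed root finding on the analytic derivatives.

    Independent numeric oracle for :func:`dm_key_points`: locates the root
    of the second derivative and the positive roots of the third derivative
    with Brent's method over (0, psi_max], where psi_max is twice the 99.99%
    loss quantile (parameter-adaptive; all derivative roots lie well inside).
    """
    a, b = params.a, params.b
    if b <= 1:
        raise DomainError(
            f"numeric key points require shape b > 1 (no interior inflection point); got b={b}"
        )
    psi_max = 2.0 * lc_quantile(params, 0.9999)

    def d2(psi: float) -> float:
        return weibull_derivatives(params, psi)[1]

    def d3(psi: float) -> float:
        return weibull_derivatives(params, psi)[2]

    lo = 1e-9 * a
    if d2(lo) <= 0 or d2(psi_max) >= 0:
        raise RuntimeError(
            "no sign change of y'' in the oracle bracket; derivative formulas inconsistent"
        )
    psi_m = brentq(d2, lo, psi_max, xtol=1e-13, rtol=8.9e-16)

    # y''' is negative at the inflection and positive at psi_max.
    if d3(psi_m) >= 0 or d3(psi_max) <= 0:
        raise RuntimeError(
            "no sign change of y''' above the inflection; derivative formulas inconsistent"
        )
    psi_l = brentq(d3, psi_m, psi_max, xtol=1e-13, rtol=8.9e-16)

    psi_e: Optional[float] = None
    lc_e: Optional[float] = None
    if b > 2:
        lo_e = psi_m * 1e-6
        if d3(lo_e) <= 0:
            raise RuntimeError(
                "no sign change of y''' below the inflection where b > 2 predicts one"
            )
        psi_e = brentq(d3, lo_e, psi_m, xtol=1e-13, rtol=8.9e-16)
        lc_e = weibull_lc(params, psi_e)
    return KeyPointSet(
        psi_m=psi_m,
        psi_l=psi_l,
        lc_m=weibull_lc(params, psi_m),
        lc_l=weibull_lc(params, psi_l),
        psi_e=psi_e,
        lc_e=lc_e,
    )


def classify_period(keypoints: KeyPointSet, psi: float) -> PeriodLabel:
    """Assign a tension to one of the four curve periods.

    Intervals are half-open with boundaries belonging to the higher period:
    stationary [0, psi_e), accelerated decline [psi_e, psi_m), decelerated
    decline [psi_m, psi_l), platform [psi_l, inf).  Requires a complete key
    point set (air-entry present, i.e. shape b > 2).
    """
    if not keypoints.complete:
        raise DomainError(
            "four-period classification requires an air-entry point, "
            "which exists only for shape b > 2"
        )
    psi = float(psi)
    if psi < 0:
        raise DomainError(f"psi must be >= 0 (tension magnitude, MPa), got {psi}")
    if psi < keypoints.psi_e:
        return PeriodLabel.STATIONARY
    if psi < keypoints.psi_m:
        return PeriodLabel.ACCELERATED_DECLINE
    if psi < keypoints.psi_l:
        return PeriodLabel.DECELERATED_DECLINE
    return PeriodLabel.PLATFORM
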