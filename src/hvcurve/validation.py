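"""Validation statistics for calculated key points against measured groups.

Two tests are provided.  A one-sample t-test asks whether a measured group
(e.g. ten stem water potentials of a drought treatment) is consistent with a
calculated key point.  The bracketing ("squeeze") test formalises the claim
that a key point lies strictly between two groups: one-sided tests of the
lower group below the point and the upper group above it, both significant
at level alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .exceptions import DomainError
from .weibull import KeyPointSet, TraditionalPoints

__all__ = [
    "GroupSample",
    "TestResult",
    "one_sample_t",
    "bracket_test",
    "method_comparison_report",
    "KEY_POINT_PAIRINGS",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05

#: Which fitted point each named experimental group is compared against:
#: (differential-method field on KeyPointSet, traditional field on
#: TraditionalPoints).
KEY_POINT_PAIRINGS: dict[str, tuple[str, str]] = {
    "air_entry": ("psi_e", "psi_12"),
    "fastest_drop": ("psi_m", "psi_50"),
    "lethal": ("psi_l", "psi_88"),
}


@dataclass(frozen=True)
class GroupSample:
    """A group of measurements (tensions in MPa or LC fractions), n >= 2."""

    group: str
    values: tuple[float, ...]

    def __post_init__(self):
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if len(vals) < 2:
            raise DomainError(f"group {self.group!r} needs n >= 2, got {len(vals)}")
        if not np.all(np.isfinite(vals)):
            raise DomainError(f"group {self.group!r} contains non-finite values")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    direction: str  # "two-sided" | "less" | "greater"
    alpha: float = DEFAULT_ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "direction": self.direction,
            "alpha": self.alpha,
            "significant": self.significant,
        }


def one_sample_t(
    sample: GroupSample,
    mu0: float,
    direction: str = "two-sided",
    alpha: float = DEFAULT_ALPHA,
) -> TestResult:
    """One-sample t-test of the group mean against a calculated point ``mu0``.

    ``direction``: "two-sided" tests inequality, "less" tests mean < mu0,
    "greater" tests mean > mu0.  A zero-variance sample is an error unless
    its common value equals ``mu0``, in which case p = 1 by convention
    (no evidence of any difference).
    """
    if direction not in ("two-sided", "less", "greater"):
        raise DomainError(f"unknown test direction {direction!r}")
    if sample.sd == 0:
        if sample.mean == mu0:
            return TestResult(0.0, sample.n - 1, 1.0, direction, alpha)
        raise DomainError(
            f"group {sample.group!r} has zero variance with mean != mu0; "
            "the t statistic is undefined"
        )
    res = sps.ttest_1samp(sample.values, popmean=mu0, alternative=direction)
    return TestResult(
        statistic=float(res.statistic),
        df=sample.n - 1,
        p_value=float(res.pvalue),
        direction=direction,
        alpha=alpha,
    )


def bracket_test(
    lower: GroupSample,
    upper: GroupSample,
    point: float,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[TestResult, TestResult, bool]:
    """Squeeze test: does ``point`` lie strictly between the two groups?

    Runs one-sided tests of the lower group mean below the point and the
    upper group mean above it; ``bracketed`` is True when both reject at
    level ``alpha``.
    """
    lower_res = one_sample_t(lower, point, direction="less", alpha=alpha)
    upper_res = one_sample_t(upper, point, direction="greater", alpha=alpha)
    return lower_res, upper_res, lower_res.significant and upper_res.significant


def method_comparison_report(
    groups: Mapping[str, GroupSample],
    keypoints: KeyPointSet,
    tm: TraditionalPoints,
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, dict]:
    """Compare each group to its differential- and traditional-method point.

    Groups are keyed by the point they should match ("air_entry",
    "fastest_drop", "lethal"); unknown keys are skipped with a log entry.
    For each pairing both calculated points are tested two-sided; a method
    is labelled "consistent" when p >= alpha, otherwise "overestimates" or
    "underestimates" according to the sign of point minus group mean.
    """
    report: dict[str, dict] = {}
    for key, sample in groups.items():
        if key not in KEY_POINT_PAIRINGS:
            logger.info("group %r has no key-point pairing; skipped", key)
            continue
        dm_field, tm_field = KEY_POINT_PAIRINGS[key]
        entry: dict[str, dict] = {}
        for method, point in (
            ("dm", getattr(keypoints, dm_field)),
            ("tm", getattr(tm, tm_field)),
        ):
            if point is None:
                logger.info("point %s absent for group %r; skipped", dm_field, key)
                continue
            res = one_sample_t(sample, point, direction="two-sided", alpha=alpha)
            if not res.significant:
                label = "consistent"
            elif point > sample.mean:
                label = "overestimates"
            else:
                label = "underestimates"
            entry[method] = {"point": point, "test": res.to_dict(), "label": label}
        report[key] = entry
    return report
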