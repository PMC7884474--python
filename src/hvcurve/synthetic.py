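"""Seeded generators emulating an air-injection vulnerability experiment.

Everything the other modules consume can be produced here with no external
data: noisy loss-of-conductivity observations on the standard 24-level
air-injection pressure schedule, raw conductance-time series obtained by
inverting LC_i = 1 - T/t_i, and Gaussian group samples around chosen key
points (mirroring the drought-treatment groups used to validate the
calculated points).

Noise model: additive Gaussian on LC, truncated to the physical range
[0, 1].  All generators are pure functions of their configuration and seed;
identical inputs give identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .hydraulics import DEFAULT_PRESSURE_SCHEDULE, InjectionSeries, InjectionStep
from .validation import GroupSample
from .weibull import WeibullParams, weibull_lc

__all__ = [
    "SimulationConfig",
    "default_pressure_schedule",
    "generate_vc_observations",
    "generate_injection_series",
    "generate_group_samples",
]

#: Loss-of-conductivity cap applied before inverting to conductance times;
#: keeps t_i = T/(1 - LC) finite at full embolism.
LC_TIME_CAP = 1.0 - 1e-4


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults for the synthetic experiment.

    The defaults reproduce the measurement design the package targets:
    the fitted curve (a = 2.23 MPa, b = 2.50), ten sampled stems, the
    24-level injection schedule, LC noise of 0.02, and a flushed reference
    conductance time of 120 s.
    """

    true_params: WeibullParams = field(
        default_factory=lambda: WeibullParams(a=2.23, b=2.50)
    )
    pressure_schedule: tuple[float, ...] = DEFAULT_PRESSURE_SCHEDULE
    noise_sd: float = 0.02
    n_samples: int = 10
    seed: Optional[int] = None
    reference_time_s: float = 120.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise DomainError(f"noise_sd must be >= 0, got {self.noise_sd}")
        sched = np.asarray(self.pressure_schedule, dtype=float)
        if sched.size < 2 or np.any(np.diff(sched) <= 0):
            raise DomainError("pressure schedule must be strictly increasing")
        if self.n_samples < 1:
            raise DomainError(f"n_samples must be >= 1, got {self.n_samples}")
        if self.reference_time_s <= 0:
            raise DomainError(
                f"reference_time_s must be > 0, got {self.reference_time_s}"
            )


def default_pressure_schedule() -> np.ndarray:
    """The 24-level air-injection schedule: 0.00-4.00 MPa at 0.20 MPa steps,
    then 4.50, 5.00 and 6.00 MPa."""
    return np.asarray(DEFAULT_PRESSURE_SCHEDULE, dtype=float)


def _require_seed(config: SimulationConfig) -> np.random.Generator:
    if config.noise_sd > 0 and config.seed is None:
        raise DomainError("a seed is required for any stochastic generation")
    return np.random.default_rng(config.seed)


def generate_vc_observations(config: SimulationConfig) -> pd.DataFrame:
    """Noisy vulnerability observations, one row per (sample, pressure level).

    LC values are the true curve plus Gaussian noise of sd ``noise_sd``,
    truncated to [0, 1].  Columns: ``sample_id``, ``psi_mpa``, ``lc``.
    """
    rng = _require_seed(config)
    sched = np.asarray(config.pressure_schedule, dtype=float)
    frames = []
    for s in range(config.n_samples):
        true_lc = weibull_lc(config.true_params, sched)
        noisy = np.clip(
            np.atleast_1d(true_lc) + rng.normal(0.0, config.noise_sd, size=sched.size),
            0.0,
            1.0,
        )
        frames.append(
            pd.DataFrame(
                {"sample_id": f"S{s:02d}", "psi_mpa": sched, "lc": noisy}
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_injection_series(config: SimulationConfig) -> list[InjectionSeries]:
    """Raw conductance-time series per sample, inverted from noisy LC.

    Times follow t_i = T/(1 - LC_i) with LC capped below 1 (cap 1 - 1e-4)
    so that fully embolised steps keep finite times; below the cap the LC
    round-trips exactly through ``lc_from_times``.
    """
    observations = generate_vc_observations(config)
    series: list[InjectionSeries] = []
    for sid, grp in observations.groupby("sample_id", sort=True):
        lc = np.minimum(grp["lc"].to_numpy(), LC_TIME_CAP)
        times = config.reference_time_s / (1.0 - lc)
        steps = tuple(
            InjectionStep(index=i, pressure_mpa=float(p), time_s=float(t))
            for i, (p, t) in enumerate(zip(grp["psi_mpa"], times))
        )
        series.append(
            InjectionSeries(
                sample_id=str(sid),
                reference_time_s=config.reference_time_s,
                steps=steps,
            )
        )
    return series


def generate_group_samples(
    center: float,
    sd: float,
    n: int = 10,
    seed: Optional[int] = None,
    group: str = "group",
) -> GroupSample:
    """Gaussian group of ``n`` measurements about ``center`` (sd ``sd``).

    Emulates a drought-treatment group summarised as mean +/- SE with
    n = 10; used to exercise the one-sample and bracketing tests.
    """
    if sd < 0:
        raise DomainError(f"sd must be >= 0, got {sd}")
    if n < 2:
        raise DomainError(f"group size must be >= 2, got {n}")
    if sd > 0 and seed is None:
        raise DomainError("a seed is required for any stochastic generation")
    rng = np.random.default_rng(seed)
    values = rng.normal(center, sd, size=n) if sd > 0 else np.full(n, center)
    return GroupSample(group=group, values=tuple(float(v) for v in values))
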