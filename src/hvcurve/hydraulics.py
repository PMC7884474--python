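"""Raw-measurement hydraulics: conductivity, loss of conductivity, water balance.

Stem-specific hydraulic conductivity is

    K_s = L * (m/t) / (A * p)        [kg m^-1 s^-1 MPa^-1]

for a segment of length ``L`` (m) and mean cross-sectional area ``A`` (m^2)
passing ``m`` kg of water in ``t`` s under pressure ``p`` (MPa).  The loss of
conductivity after an air injection is LC = (K_m - K_s)/K_m against the
flushed maximum K_m, which for fixed geometry and pressure reduces
algebraically to LC_i = 1 - T/t_i in terms of conductance times alone
(T being the time recorded at K_m).

Water balance of a transpiring stem: xylem water gain
WG = K_m * dPsi * A * (1 - LC) / L and leaf water loss WL = E * LA, with the
transpiration rate E in mol m^-2 s^-1 converted to kg s^-1 through the molar
mass of water by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError

__all__ = [
    "SegmentGeometry",
    "FlowMeasurement",
    "InjectionStep",
    "InjectionSeries",
    "WaterBalanceRecord",
    "DEFAULT_PRESSURE_SCHEDULE",
    "MOLAR_MASS_WATER",
    "specific_conductivity",
    "lc_from_conductivities",
    "lc_from_times",
    "water_gain",
    "water_loss",
    "water_balance",
    "head_to_pressure",
]

#: Air-injection pressure schedule (MPa): 0.00-4.00 at 0.20 MPa steps, then
#: 4.50, 5.00, 6.00 — 24 levels, injection indices 0..23.
DEFAULT_PRESSURE_SCHEDULE: tuple[float, ...] = tuple(
    np.round(np.arange(0.0, 4.01, 0.2), 10)
) + (4.5, 5.0, 6.0)

#: Molar mass of water, kg mol^-1.
MOLAR_MASS_WATER = 0.018015

_RHO_WATER = 1000.0  # kg m^-3
_G = 9.81  # m s^-2


@dataclass(frozen=True)
class SegmentGeometry:
    """Stem segment: length (m) and mean cross-sectional area of both ends (m^2)."""

    length_m: float
    area_m2: float

    def __post_init__(self):
        if self.length_m <= 0:
            raise DomainError(f"segment length must be > 0 m, got {self.length_m}")
        if self.area_m2 <= 0:
            raise DomainError(f"segment area must be > 0 m^2, got {self.area_m2}")


@dataclass(frozen=True)
class FlowMeasurement:
    """One conductance measurement: water mass (kg), duration (s), pressure (MPa)."""

    mass_kg: float
    time_s: float
    pressure_mpa: float

    def __post_init__(self):
        if self.mass_kg < 0:
            raise DomainError(f"water mass must be >= 0 kg, got {self.mass_kg}")
        if self.time_s <= 0:
            raise DomainError(f"measurement time must be > 0 s, got {self.time_s}")
        if self.pressure_mpa <= 0:
            raise DomainError(f"driving pressure must be > 0 MPa, got {self.pressure_mpa}")


@dataclass(frozen=True)
class InjectionStep:
    """One air-injection step: index, applied pressure (MPa), conductance time (s)."""

    index: int
    pressure_mpa: float
    time_s: float


@dataclass(frozen=True)
class InjectionSeries:
    """Air-injection record for one sample.

    ``reference_time_s`` is the conductance time measured at the flushed
    maximum conductivity K_m.  Steps with ``time_s`` below it imply
    supra-maximal conductance; they are flagged downstream, not rejected.
    """

    sample_id: str
    reference_time_s: float
    steps: Sequence[InjectionStep] = field(default_factory=tuple)

    def __post_init__(self):
        if self.reference_time_s <= 0:
            raise DomainError(
                f"reference time must be > 0 s, got {self.reference_time_s}"
            )
        pressures = [s.pressure_mpa for s in self.steps]
        if any(b < a for a, b in zip(pressures, pressures[1:])):
            raise DomainError("injection pressures must be non-decreasing")


@dataclass(frozen=True)
class WaterBalanceRecord:
    """Inputs of the stem water balance; outputs via :func:`water_balance`.

    ``delta_psi_mpa`` is the magnitude of the soil-to-stem water potential
    difference (tension convention).
    """

    k_m: float
    delta_psi_mpa: float
    area_m2: float
    lc: float
    length_m: float
    e_mol_m2_s: float
    leaf_area_m2: float


def specific_conductivity(geom: SegmentGeometry, flow: FlowMeasurement) -> float:
    """Stem-specific hydraulic conductivity K_s = L*(m/t)/(A*p), kg m^-1 s^-1 MPa^-1."""
    q_m = flow.mass_kg / flow.time_s
    return geom.length_m * q_m / (geom.area_m2 * flow.pressure_mpa)


def lc_from_conductivities(k_m: float, k_s_i: float) -> float:
    """Loss of conductivity (K_m - K_s)/K_m relative to the flushed maximum.

    Negative results (measured conductivity above the flushed maximum) are
    returned as-is with a warning; clamping is a user decision.
    """
    if k_m <= 0:
        raise DomainError(f"maximum conductivity K_m must be > 0, got {k_m}")
    if k_s_i < 0:
        raise DomainError(f"conductivity must be >= 0, got {k_s_i}")
    lc = (k_m - k_s_i) / k_m
    if lc < 0:
        warnings.warn(
            f"LC = {lc:.4g} < 0: measured conductivity exceeds the flushed maximum",
            stacklevel=2,
        )
    return lc


def lc_from_times(series: InjectionSeries) -> pd.DataFrame:
    """Per-step loss of conductivity LC_i = 1 - T/t_i from conductance times.

    Returns a frame with columns ``step_index``, ``pressure_mpa``, ``lc``
    and a boolean ``supra_maximal`` flag marking steps where t_i < T
    (negative LC, a measurement anomaly that is reported, never clamped).
    """
    times = np.array([s.time_s for s in series.steps], dtype=float)
    if np.any(times <= 0):
        raise DomainError("all conductance times must be > 0 s")
    lc = 1.0 - series.reference_time_s / times
    flags = lc < 0
    if flags.any():
        warnings.warn(
            f"{int(flags.sum())} step(s) of sample {series.sample_id!r} show "
            "supra-maximal conductance (t_i < T, LC < 0)",
            stacklevel=2,
        )
    return pd.DataFrame(
        {
            "step_index": [s.index for s in series.steps],
            "pressure_mpa": [s.pressure_mpa for s in series.steps],
            "lc": lc,
            "supra_maximal": flags,
        }
    )


def water_gain(
    k_m: float, delta_psi: float, area: float, lc: float, length: float
) -> float:
    """Xylem water gain WG = K_m * dPsi * A * (1 - LC) / L, kg s^-1."""
    if length <= 0:
        raise DomainError(f"segment length must be > 0 m, got {length}")
    if not 0 <= lc <= 1:
        raise DomainError(f"loss of conductivity must lie in [0, 1], got {lc}")
    return k_m * delta_psi * area * (1.0 - lc) / length


def water_loss(e: float, leaf_area: float, *, convert_to_kg: bool = True) -> float:
    """Leaf water loss WL = E * LA.

    With ``convert_to_kg`` (the default) the transpiration rate E
    (mol m^-2 s^-1) is converted through the molar mass of water, giving WL
    in kg s^-1 and dimensional consistency with the water gain; disabling it
    returns the bare molar flux E*LA in mol s^-1.
    """
    if e < 0:
        raise DomainError(f"transpiration rate must be >= 0, got {e}")
    if leaf_area < 0:
        raise DomainError(f"leaf area must be >= 0, got {leaf_area}")
    wl = e * leaf_area
    return wl * MOLAR_MASS_WATER if convert_to_kg else wl


def water_balance(
    record: WaterBalanceRecord, *, convert_to_kg: bool = True
) -> dict[str, float]:
    """Water gain, loss, and their net difference for one stem record."""
    wg = water_gain(
        record.k_m,
        record.delta_psi_mpa,
        record.area_m2,
        record.lc,
        record.length_m,
    )
    wl = water_loss(record.e_mol_m2_s, record.leaf_area_m2, convert_to_kg=convert_to_kg)
    return {"wg": wg, "wl": wl, "net": wg - wl}


def head_to_pressure(height_m: float) -> float:
    """Hydrostatic pressure (MPa) of a water column of the given height (m)."""
    if height_m < 0:
        raise DomainError(f"column height must be >= 0 m, got {height_m}")
    return _RHO_WATER * _G * height_m * 1e-6
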