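"""CSV readers, the JSON analysis report, and the end-to-end pipeline.

CSV dialects (UTF-8, headered):

* vulnerability observations — ``sample_id, psi_mpa, lc``
* injection series — ``sample_id, step_index, pressure_mpa, time_s,
  reference_time_s`` (the reference time repeats per sample's rows)
* conductivity records — ``sample_id, length_m, area_m2, mass_kg, time_s,
  pressure_mpa``
* validation groups — ``group, sample_id, variable, value`` with
  ``variable`` in {psi, lc}

Water-potential columns (``psi_mpa``) hold positive tension magnitudes.
Unknown extra columns are tolerated (logged), missing or out-of-range
values are errors carrying the offending line number.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import DomainError, FitError, PipelineError, ValidationError
from .fitting import FitResult, bootstrap_ci, fit_weibull
from .hydraulics import InjectionSeries, InjectionStep
from .validation import GroupSample, method_comparison_report
from .weibull import (
    KeyPointSet,
    TraditionalPoints,
    classify_period,
    dm_key_points,
    tm_points,
)

__all__ = [
    "SCHEMA_VERSION",
    "AnalysisReport",
    "read_vc_csv",
    "read_injection_csv",
    "read_conductivity_csv",
    "read_groups_csv",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

#: Major.minor version of the JSON report schema; readers reject unknown majors.
SCHEMA_VERSION = "1.0"


# --------------------------------------------------------------------- CSV in
def _read_table(path, required: dict[str, type]) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path)
    missing = set(required) - set(frame.columns)
    if missing:
        raise ValidationError(f"{path.name}: missing column(s) {sorted(missing)}")
    extra = set(frame.columns) - set(required)
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s", path.name, sorted(extra))
    return frame


def _row_check(frame: pd.DataFrame, column: str, ok: pd.Series, message: str, path):
    bad = frame.index[~ok]
    if len(bad):
        # header is line 1, first data row line 2
        line = int(bad[0]) + 2
        raise ValidationError(
            f"{Path(path).name} line {line}: {column} {message} "
            f"(value {frame.loc[bad[0], column]!r})"
        )


def read_vc_csv(path) -> pd.DataFrame:
    """Vulnerability observations: columns sample_id, psi_mpa, lc."""
    frame = _read_table(path, {"sample_id": str, "psi_mpa": float, "lc": float})
    for col in ("psi_mpa", "lc"):
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
        _row_check(frame, col, frame[col].notna(), "is not numeric", path)
    _row_check(frame, "psi_mpa", frame["psi_mpa"] >= 0, "must be >= 0 (MPa tension)", path)
    _row_check(frame, "lc", (frame["lc"] >= 0) & (frame["lc"] <= 1), "must lie in [0, 1]", path)
    return frame[["sample_id", "psi_mpa", "lc"]]


def read_injection_csv(path) -> list[InjectionSeries]:
    """Air-injection series: sample_id, step_index, pressure_mpa, time_s,
    reference_time_s (constant within a sample)."""
    frame = _read_table(
        path,
        {
            "sample_id": str,
            "step_index": int,
            "pressure_mpa": float,
            "time_s": float,
            "reference_time_s": float,
        },
    )
    series = []
    for sid, grp in frame.groupby("sample_id", sort=True):
        ref = grp["reference_time_s"].unique()
        if len(ref) != 1:
            raise ValidationError(
                f"sample {sid!r}: reference_time_s must be constant within a sample"
            )
        grp = grp.sort_values("step_index")
        steps = tuple(
            InjectionStep(index=int(r.step_index), pressure_mpa=float(r.pressure_mpa),
                          time_s=float(r.time_s))
            for r in grp.itertuples()
        )
        series.append(
            InjectionSeries(sample_id=str(sid), reference_time_s=float(ref[0]), steps=steps)
        )
    return series


def read_conductivity_csv(path) -> pd.DataFrame:
    """Segment conductivity records: sample_id, length_m, area_m2, mass_kg,
    time_s, pressure_mpa."""
    frame = _read_table(
        path,
        {
            "sample_id": str,
            "length_m": float,
            "area_m2": float,
            "mass_kg": float,
            "time_s": float,
            "pressure_mpa": float,
        },
    )
    for col, low in (("length_m", 0), ("area_m2", 0), ("time_s", 0), ("pressure_mpa", 0)):
        _row_check(frame, col, frame[col] > low, f"must be > {low}", path)
    _row_check(frame, "mass_kg", frame["mass_kg"] >= 0, "must be >= 0", path)
    return frame


def read_groups_csv(path) -> dict[str, dict[str, GroupSample]]:
    """Validation groups keyed by variable ("psi"|"lc") then group label."""
    frame = _read_table(
        path, {"group": str, "sample_id": str, "variable": str, "value": float}
    )
    bad = ~frame["variable"].isin(["psi", "lc"])
    _row_check(frame, "variable", ~bad, "must be 'psi' or 'lc'", path)
    out: dict[str, dict[str, GroupSample]] = {}
    for (var, grp_label), grp in frame.groupby(["variable", "group"], sort=True):
        out.setdefault(str(var), {})[str(grp_label)] = GroupSample(
            group=str(grp_label), values=tuple(grp["value"].astype(float))
        )
    return out


# ------------------------------------------------------------------ reporting
def _keypoints_dict(kp: KeyPointSet) -> dict:
    return {
        "psi_e": kp.psi_e,
        "psi_m": kp.psi_m,
        "psi_l": kp.psi_l,
        "lc_e": kp.lc_e,
        "lc_m": kp.lc_m,
        "lc_l": kp.lc_l,
    }


def _tm_dict(tm: TraditionalPoints) -> dict:
    return {"psi_12": tm.psi_12, "psi_50": tm.psi_50, "psi_88": tm.psi_88}


@dataclass
class AnalysisReport:
    """Serializable end-to-end result: fit, key points, classifications, stats.

    Round-trips losslessly through JSON; the schema carries a major.minor
    version and readers reject unknown majors.
    """

    fit: dict
    dm: Optional[dict] = None
    tm: Optional[dict] = None
    periods: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisReport":
        version = data.get("schema_version", "")
        major = version.split(".")[0]
        if major != SCHEMA_VERSION.split(".")[0]:
            raise ValidationError(
                f"unsupported report schema version {version!r}; "
                f"this reader handles major {SCHEMA_VERSION.split('.')[0]}"
            )
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls.from_dict(json.loads(text))


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(
    vc_path,
    groups_path=None,
    *,
    method: str = "both",
    alpha: float = 0.05,
    n_boot: int = 0,
    seed: Optional[int] = None,
    classify_psi: Sequence[float] = (),
) -> AnalysisReport:
    """Fit a vulnerability curve from CSV and assemble the full report.

    Stages: read -> fit (optionally with a bootstrap of size ``n_boot``) ->
    key points by the requested method(s) -> optional period classification
    of the queried tensions -> optional group validation statistics.
    Each stage failure is re-raised as a :class:`PipelineError` naming the
    stage.
    """
    if method not in ("dm", "tm", "both"):
        raise PipelineError("options", f"unknown method {method!r}")

    try:
        observations = read_vc_csv(vc_path)
    except (ValidationError, OSError) as exc:
        raise PipelineError("read", str(exc)) from exc

    try:
        if n_boot:
            fit = bootstrap_ci(observations, n_boot=n_boot, seed=seed)
        else:
            fit = fit_weibull(observations)
    except (FitError, DomainError, ValidationError) as exc:
        raise PipelineError("fit", str(exc)) from exc

    fit_block = {
        "a": fit.params.a,
        "b": fit.params.b,
        "r_squared": fit.r_squared,
        "n_obs": fit.n_obs,
        "ci_a": list(fit.ci_a) if fit.ci_a else None,
        "ci_b": list(fit.ci_b) if fit.ci_b else None,
        "seed": fit.seed,
    }

    dm_block = tm_block = None
    keypoints = None
    try:
        if method in ("dm", "both"):
            keypoints = dm_key_points(fit.params)
            dm_block = _keypoints_dict(keypoints)
        if method in ("tm", "both"):
            tm_block = _tm_dict(tm_points(fit.params))
    except DomainError as exc:
        raise PipelineError("keypoints", str(exc)) from exc

    periods: dict[str, str] = {}
    if classify_psi:
        if keypoints is None:
            raise PipelineError(
                "classify", "period classification requires the differential method"
            )
        try:
            for psi in classify_psi:
                periods[f"{float(psi):g}"] = classify_period(keypoints, float(psi)).value
        except DomainError as exc:
            raise PipelineError("classify", str(exc)) from exc

    stats_block: dict = {}
    if groups_path is not None:
        if keypoints is None or tm_block is None:
            raise PipelineError(
                "validate", "group validation requires both methods (method='both')"
            )
        try:
            groups = read_groups_csv(groups_path)
            psi_groups = groups.get("psi", {})
            stats_block = method_comparison_report(
                psi_groups, keypoints, tm_points(fit.params), alpha=alpha
            )
        except (ValidationError, DomainError) as exc:
            raise PipelineError("validate", str(exc)) from exc

    provenance = {
        "vc_path": str(vc_path),
        "vc_sha256": _sha256(vc_path),
        "groups_path": str(groups_path) if groups_path else None,
        "groups_sha256": _sha256(groups_path) if groups_path else None,
        "seed": seed,
        "alpha": alpha,
        "method": method,
        "n_boot": n_boot,
        "version": __version__,
    }
    logger.info(
        "pipeline: input %s (sha256 %s), seed %s, method %s, version %s",
        provenance["vc_path"], provenance["vc_sha256"][:12], seed, method, __version__,
    )
    return AnalysisReport(
        fit=fit_block,
        dm=dm_block,
        tm=tm_block,
        periods=periods,
        stats=stats_block,
        provenance=provenance,
    )
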