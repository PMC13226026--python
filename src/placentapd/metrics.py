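"""Exploratory pharmacodynamic metrics: recovery slope and Functional Recovery Index.

Recovery slope: per-subject ordinary-least-squares slope of a marker against
gestational day, sign-flipped for markers where a decrease means improvement
(SBP, proteinuria, UtA-RI), so a positive adjusted slope always reads as
movement toward the healthy phenotype.

FRI (at the study endpoint):

    FRI = 100 * (X_i - mean_PE) / (mean_control - mean_PE)

where X_i is a treated subject's value and the reference means are the control
and untreated-disease group means.  100% is complete normalization, 0% no
improvement over the disease phenotype; values outside [0, 100] are reported
as-is (negative = further deterioration), never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import StudyConfig
from .errors import DegenerateReferenceError, UndefinedSlopeError

METRIC_COLUMNS = ["dam_id", "group", "marker", "beta_raw", "beta_adjusted",
                  "n_points", "rss", "fri_percent"]


@dataclass(frozen=True)
class MarkerOrientation:
    """Direction in which a marker moves under recovery."""

    marker: str
    increase_is_recovery: bool


@dataclass(frozen=True)
class SubjectSlope:
    """Per-subject OLS slope with its directional adjustment."""

    dam_id: str
    marker: str
    beta_raw: float          # units/day
    beta_adjusted: float     # +beta or -beta per orientation
    n_points: int
    rss: float


@dataclass(frozen=True)
class FriValue:
    dam_id: str
    marker: str
    x_i: float
    mean_control: float
    mean_pe: float
    fri_percent: float


@dataclass(frozen=True)
class FriSummary:
    marker: str
    values: tuple[FriValue, ...]
    mean: float
    sem: float


def subject_slope(gd, values, orientation: MarkerOrientation,
                  dam_id: str = "") -> SubjectSlope:
    """OLS slope of value on gestational day for one subject."""
    gd = np.asarray(gd, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(gd) < 2 or len(np.unique(gd)) < 2:
        raise UndefinedSlopeError("need at least 2 distinct gestational days")
    xc = gd - gd.mean()
    beta = float(np.dot(xc, values) / np.dot(xc, xc))
    intercept = values.mean() - beta * gd.mean()
    resid = values - (intercept + beta * gd)
    adjusted = beta if orientation.increase_is_recovery else -beta
    return SubjectSlope(dam_id=dam_id, marker=orientation.marker, beta_raw=beta,
                        beta_adjusted=adjusted, n_points=len(gd),
                        rss=float(np.dot(resid, resid)))


def fri(x_i: float, mean_control: float, mean_pe: float,
        guard_rel: float = 1e-9) -> float:
    """Functional Recovery Index in percent (unbounded by design)."""
    gap = mean_control - mean_pe
    guard = guard_rel * max(abs(mean_control), 1.0)
    if abs(gap) <= guard:
        raise DegenerateReferenceError(
            f"reference means too close (|gap| = {abs(gap):.3g} <= guard {guard:.3g})"
        )
    return float(100.0 * (x_i - mean_pe) / gap)


def group_fri_summary(final_values: pd.DataFrame, marker: str,
                      guard_rel: float = 1e-9) -> FriSummary:
    """FRI per treated subject at the final GD, with mean +/- SEM.

    *final_values* holds columns (dam_id, group, value) at the endpoint; the
    reference means are computed from the control and disease arms of the same
    table (i.e. from measured values, as an experimenter would).
    """
    by_group = {g: sub for g, sub in final_values.groupby("group")}
    for g in ("control", "disease", "treated"):
        if g not in by_group or len(by_group[g]) == 0:
            raise DegenerateReferenceError(f"group {g!r} empty or absent at final GD")
    mean_control = float(by_group["control"]["value"].mean())
    mean_pe = float(by_group["disease"]["value"].mean())
    values = []
    for _, row in by_group["treated"].sort_values("dam_id").iterrows():
        values.append(FriValue(
            dam_id=row["dam_id"], marker=marker, x_i=float(row["value"]),
            mean_control=mean_control, mean_pe=mean_pe,
            fri_percent=fri(float(row["value"]), mean_control, mean_pe, guard_rel),
        ))
    arr = np.array([v.fri_percent for v in values])
    sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return FriSummary(marker=marker, values=tuple(values),
                      mean=float(arr.mean()), sem=sem)


def compute_pd_metrics(measured: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Per-subject adjusted slopes for all markers and FRIs for treated subjects.

    Slopes use each marker's own sampling grid (systemic markers over the
    GD7-18 grid, imaging markers over GD14-18).  FRI is computed at the final
    gestational day against measured control/disease group means; it is NaN
    for non-treated subjects, for whom the index is not defined.
    """
    design = config.design
    rows = []
    for cal in config.markers:
        orientation = MarkerOrientation(cal.name, cal.increase_is_recovery)
        sub = measured[measured["marker"] == cal.name]
        if sub.empty:
            continue
        final_gd = max(design.grid(cal.grid))
        final = sub[sub["gd"] == final_gd][["dam_id", "group", "value"]]
        summary = group_fri_summary(final, cal.name, config.analysis.fri_guard_rel)
        fri_by_dam = {v.dam_id: v.fri_percent for v in summary.values}
        for (dam_id, group), dsub in sub.groupby(["dam_id", "group"], sort=True):
            dsub = dsub.dropna(subset=["value"])
            slope = subject_slope(dsub["gd"].to_numpy(), dsub["value"].to_numpy(),
                                  orientation, dam_id=dam_id)
            rows.append({
                "dam_id": dam_id, "group": group, "marker": cal.name,
                "beta_raw": slope.beta_raw, "beta_adjusted": slope.beta_adjusted,
                "n_points": slope.n_points, "rss": slope.rss,
                "fri_percent": fri_by_dam.get(dam_id, np.nan),
            })
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)
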