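"""Longitudinal in-vivo endpoints and clinical-cohort survival analysis.

Caliper tumor volumes, day-1 normalization of growth series,
last-observation-carried-forward (LOCF) imputation of bioluminescence
flux, tumor tripling time as a time-to-event endpoint, arm-level
Kaplan-Meier/log-rank summaries, and the median-split overall-survival
analysis used for expression cohorts (high = expression strictly above
the median), with log-rank p and a univariate Cox hazard ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    GroupingError,
    NormalizationError,
    SampleSizeError,
    ValidationError,
)
from .stats_core import KMCurve, TestResult, cox_univariate, km_curve, logrank_test

__all__ = [
    "GrowthSeries",
    "TriplingRecord",
    "caliper_volume",
    "normalize_to_baseline",
    "locf_impute",
    "tripling_time",
    "arm_endpoint_analysis",
    "median_split_survival",
]

TRIPLING_FACTOR = 3.0


@dataclass
class GrowthSeries:
    """One animal's longitudinal tumor measurements.

    ``days`` strictly increasing; ``values`` are volumes (mm^3) or total
    flux (photons/s). The first measured day is the treatment baseline.
    """

    animal: str
    arm: str
    days: np.ndarray
    values: np.ndarray
    kind: str = "volume"
    imputed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.days.size != self.values.size:
            raise ValidationError("days and values must have equal length")
        if np.any(np.diff(self.days) <= 0):
            raise ValidationError(f"days must be strictly increasing ({self.animal})")
        if np.any(self.values[np.isfinite(self.values)] < 0):
            raise ValidationError("measurements must be non-negative")
        if self.imputed is None:
            self.imputed = np.zeros(self.days.size, dtype=bool)


@dataclass
class TriplingRecord:
    animal: str
    arm: str
    tripling_day: float | None
    censored: bool
    last_day: float


def caliper_volume(length: float, width: float) -> float:
    """Ellipsoid caliper volume, (pi/6) * L * W^2 in mm^3.

    Length is the larger axis; reversed inputs are swapped (the formula
    squares the smaller one).
    """
    if length < 0 or width < 0:
        raise ValidationError("caliper dimensions must be non-negative")
    if width > length:
        length, width = width, length
    return float(np.pi / 6.0 * length * width * width)


def normalize_to_baseline(series: GrowthSeries) -> GrowthSeries:
    """Express every measurement as percent of the first measured day."""
    baseline = series.values[0]
    if not np.isfinite(baseline) or baseline <= 0:
        raise NormalizationError(
            f"baseline measurement must be positive ({series.animal})")
    return GrowthSeries(animal=series.animal, arm=series.arm, days=series.days,
                        values=series.values / baseline * 100.0,
                        kind=series.kind, imputed=series.imputed.copy())


def locf_impute(series: GrowthSeries, schedule=None) -> GrowthSeries:
    """Fill missing scheduled time points with the last observed value.

    ``schedule`` extends the series to later scheduled days (e.g. the
    cohort's imaging days after an animal was euthanized); within-series
    NaNs are filled the same way. Observed values are never altered;
    imputed points are flagged. A missing value with no prior observation
    is an error.
    """
    days = series.days
    values = series.values.copy()
    imputed = series.imputed.copy()
    if schedule is not None:
        schedule = np.asarray(schedule, dtype=float)
        extra = schedule[schedule > days[-1] + 1e-12]
        days = np.concatenate([days, extra])
        values = np.concatenate([values, np.full(extra.size, np.nan)])
        imputed = np.concatenate([imputed, np.zeros(extra.size, dtype=bool)])
    if not np.isfinite(values[0]):
        raise ValidationError(
            f"first time point missing; nothing to carry forward ({series.animal})")
    for i in range(1, values.size):
        if not np.isfinite(values[i]):
            values[i] = values[i - 1]
            imputed[i] = True
    return GrowthSeries(animal=series.animal, arm=series.arm, days=days,
                        values=values, kind=series.kind, imputed=imputed)


def tripling_time(series: GrowthSeries) -> TriplingRecord:
    """Earliest measured day with value >= 3x the first-day value.

    The crossing is evaluated only at measured days (no interpolation);
    an animal that never triples is censored at its last measured day.
    """
    if series.days.size < 2:
        raise SampleSizeError(f"need >= 2 measurements ({series.animal})")
    baseline = series.values[0]
    if not np.isfinite(baseline) or baseline <= 0:
        raise ValidationError(f"baseline must be positive ({series.animal})")
    crossed = np.nonzero(series.values >= TRIPLING_FACTOR * baseline)[0]
    if crossed.size:
        return TriplingRecord(animal=series.animal, arm=series.arm,
                              tripling_day=float(series.days[crossed[0]]),
                              censored=False, last_day=float(series.days[-1]))
    return TriplingRecord(animal=series.animal, arm=series.arm,
                          tripling_day=None, censored=True,
                          last_day=float(series.days[-1]))


def _tripling_event_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        time = r.last_day if r.censored else r.tripling_day
        rows.append({"subject": r.animal, "group": r.arm,
                     "time_days": float(time), "event": int(not r.censored)})
    return pd.DataFrame(rows)


def arm_endpoint_analysis(records_or_events, arms=None) -> dict:
    """Per-arm KM medians plus all pairwise log-rank comparisons.

    Accepts either a sequence of TriplingRecord or an event table with
    columns (subject, group, time_days, event). Returns a dict with
    ``curves`` (arm -> KMCurve), ``summary`` (DataFrame of arm, n,
    events, median), and ``pairwise`` (DataFrame of arm_a, arm_b, chi2, p).
    """
    if isinstance(records_or_events, pd.DataFrame):
        events = records_or_events
    else:
        events = _tripling_event_frame(records_or_events)
    required = {"group", "time_days", "event"}
    if not required.issubset(events.columns):
        raise ValidationError(f"event table needs columns {sorted(required)}")
    if arms is None:
        arms = sorted(events["group"].unique())
    if len(arms) < 2:
        raise GroupingError("need >= 2 arms to compare")
    curves: dict = {}
    summary = []
    for arm in arms:
        sub = events[events["group"] == arm]
        if sub.empty:
            raise GroupingError(f"arm {arm!r} has no records")
        curve = km_curve(sub["time_days"], sub["event"])
        curves[arm] = curve
        summary.append({"arm": arm, "n": int(len(sub)),
                        "events": int(sub["event"].sum()),
                        "median": curve.median})
    pairwise = []
    for i in range(len(arms)):
        for j in range(i + 1, len(arms)):
            a, b = arms[i], arms[j]
            sub = events[events["group"].isin([a, b])]
            res = logrank_test(sub["time_days"], sub["event"], sub["group"],
                               group_labels=[a, b])
            pairwise.append({"arm_a": a, "arm_b": b,
                             "chi2": res.statistic, "p": res.p_value})
    return {"curves": curves, "summary": pd.DataFrame(summary),
            "pairwise": pd.DataFrame(pairwise)}


def median_split_survival(data: pd.DataFrame) -> dict:
    """Median-cutoff expression stratification with KM, log-rank and Cox.

    ``data`` has columns (expression, os_days, os_event). High group:
    expression strictly above the median; ties go to the low group.
    Returns group assignment, per-group KM curves and medians, the
    log-rank result, and the univariate Cox hazard ratio (high vs low)
    with its Wald 95% CI.
    """
    required = {"expression", "os_days", "os_event"}
    if not required.issubset(data.columns):
        raise ValidationError(f"need columns {sorted(required)}")
    if len(data) < 4:
        raise SampleSizeError("need >= 4 patients for a median split")
    expr = data["expression"].astype(float)
    if expr.nunique() <= 1:
        raise GroupingError("expression is constant; median split impossible")
    cutoff = float(expr.median())
    high = expr > cutoff
    if high.all() or (~high).all():
        raise GroupingError("median split produced an empty group")
    group = np.where(high, "high", "low")
    curves = {
        label: km_curve(data.loc[group == label, "os_days"],
                        data.loc[group == label, "os_event"])
        for label in ("low", "high")
    }
    logrank = logrank_test(data["os_days"], data["os_event"], group,
                           group_labels=["low", "high"])
    cox = cox_univariate(data["os_days"].to_numpy(dtype=float),
                         data["os_event"].to_numpy(),
                         high.to_numpy().astype(int))
    return {"cutoff": cutoff, "group": pd.Series(group, index=data.index),
            "curves": curves, "logrank": logrank, "cox": cox}
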