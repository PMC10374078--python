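"""Validation indicators, key performance indicators and income projections.

From an event trace this module computes the department's indicator set:

* ``DailyMRIexamTime`` — on-table minutes per exam, averaged per day;
* ``MRIexamPrepTime`` — scanner preparation minutes per exam, per day;
* ``DailyOverTime`` — minutes by which a scanner's last off-table time
  exceeds the 23:00 close (clamped at zero), averaged across scanners;
* ``DailyCoilChangeOccurrence`` — mounted-coil transitions per day;
* ``DailyScanUtilRate`` — occupied minutes over the 16-hour service day;
* ``WaitExamDay`` — days from booking an appointment to lying on the table,
  per coil.

It also carries the capacity-expansion arithmetic: extra daily exams are
reimbursed in Taiwan NHI global-budget points (6,500 per exam without
contrast, 11,500 with), converted to USD at a configurable point value and
exchange rate.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "KPIReport",
    "IncomeProjection",
    "TraceError",
    "POINTS_WITHOUT_CONTRAST",
    "POINTS_WITH_CONTRAST",
    "compute_kpis",
    "impute_exam_time",
    "points_and_income",
    "percent_increase",
    "saved_minutes_per_day",
    "wait_time_reduction",
    "format_duration",
]

#: NHI global-budget points per MRI examination.
POINTS_WITHOUT_CONTRAST = 6_500
POINTS_WITH_CONTRAST = 11_500

_SERVICE_MINUTES = 16 * 60
_CLOSE_TIME = dt.time(23, 0)


class TraceError(ValueError):
    """Raised for malformed event traces."""


@dataclass
class KPIReport:
    """Daily and per-coil indicator aggregates for one simulated month."""

    daily_exam_time_mean_sd: tuple[float, float]
    prep_time_mean_sd: tuple[float, float]
    daily_overtime_mean_sd: tuple[float, float]
    daily_coil_changes_mean_sd: tuple[float, float]
    utilization_pct: dict[str, float]
    wait_days: dict[str, float]
    total_exams: int
    patient_type_counts: dict[str, int]
    daily_values: dict[str, list[float]] = field(default_factory=dict, repr=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("DailyMRIexamTime", *self.daily_exam_time_mean_sd, ""),
            ("MRIexamPrepTime", *self.prep_time_mean_sd, ""),
            ("DailyOverTime", *self.daily_overtime_mean_sd, ""),
            ("DailyCoilChangeOccurrence", *self.daily_coil_changes_mean_sd, ""),
        ]
        for scanner, pct in sorted(self.utilization_pct.items()):
            rows.append((f"DailyScanUtilRate[{scanner}]", pct, float("nan"), "%"))
        for coil, days in sorted(self.wait_days.items()):
            rows.append((f"WaitExamDay[{coil}]", days, float("nan"), "days"))
        rows.append(("TotalExams", float(self.total_exams), float("nan"), "n"))
        return pd.DataFrame(rows, columns=["indicator", "mean", "sd", "units"])


@dataclass
class IncomeProjection:
    """Monthly reimbursement gain from extra daily examinations."""

    added_per_day: int
    month_days: int
    points_without_contrast: int
    points_with_contrast: int
    usd_without: int
    usd_with: int
    pct_increase: float | None = None


def _mean_sd(values) -> tuple[float, float]:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return 0.0, 0.0
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def compute_kpis(trace: pd.DataFrame, requests=None, close_time: dt.time = _CLOSE_TIME) -> KPIReport:
    """Aggregate an event trace into the indicator set.

    An empty trace yields a report of zeros.  Rows whose off-table time does
    not exceed their on-table time are rejected with their row index.
    """
    if trace.empty:
        return KPIReport(
            daily_exam_time_mean_sd=(0.0, 0.0),
            prep_time_mean_sd=(0.0, 0.0),
            daily_overtime_mean_sd=(0.0, 0.0),
            daily_coil_changes_mean_sd=(0.0, 0.0),
            utilization_pct={},
            wait_days={},
            total_exams=0,
            patient_type_counts={},
        )
    bad = trace.index[trace["table_off"] <= trace["table_on"]]
    if len(bad):
        raise TraceError(f"table_off <= table_on at row(s) {list(bad)}")

    df = trace.copy()
    df["exam_minutes"] = (df["table_off"] - df["table_on"]).dt.total_seconds() / 60.0
    df["prep_minutes"] = (df["table_on"] - df["prep_start"]).dt.total_seconds() / 60.0
    df["occupied_minutes"] = (df["table_off"] - df["prep_start"]).dt.total_seconds() / 60.0

    daily_exam = df.groupby("day")["exam_minutes"].mean()
    daily_prep = df.groupby("day")["prep_minutes"].mean()
    daily_changes = df.groupby("day")["coil_changed"].sum().astype(float)

    # overtime: per scanner-day, last off-table past the close, clamped at 0,
    # then averaged across scanners within each day
    close = df["day"].map(lambda d: dt.datetime.combine(d, close_time))
    df["past_close_minutes"] = (
        (df["table_off"] - pd.to_datetime(close)).dt.total_seconds() / 60.0
    )
    per_scanner_day = df.groupby(["day", "scanner_id"])["past_close_minutes"].max()
    daily_overtime = per_scanner_day.clip(lower=0.0).groupby("day").mean()

    n_days = df["day"].nunique()
    util = (
        df.groupby("scanner_id")["occupied_minutes"].sum()
        / (n_days * _SERVICE_MINUTES)
        * 100.0
    ).clip(upper=100.0)

    df["wait_days"] = (df["table_on"] - df["booking"]).dt.total_seconds() / 86400.0
    wait = df.groupby("coil")["wait_days"].mean()

    return KPIReport(
        daily_exam_time_mean_sd=_mean_sd(daily_exam),
        prep_time_mean_sd=_mean_sd(daily_prep),
        daily_overtime_mean_sd=_mean_sd(daily_overtime),
        daily_coil_changes_mean_sd=_mean_sd(daily_changes),
        utilization_pct={s: float(v) for s, v in util.items()},
        wait_days={c: float(v) for c, v in wait.items()},
        total_exams=int(len(df)),
        patient_type_counts=df["patient_type"].value_counts().to_dict(),
        daily_values={
            "DailyMRIexamTime": daily_exam.tolist(),
            "MRIexamPrepTime": daily_prep.tolist(),
            "DailyOverTime": daily_overtime.tolist(),
            "DailyCoilChangeOccurrence": daily_changes.tolist(),
        },
    )


def impute_exam_time(records: pd.DataFrame) -> pd.DataFrame:
    """Mean-impute exam durations for rows missing on/off-table times.

    ``records`` needs ``table_on``/``table_off`` columns; a ``duration_minutes``
    column is (re)computed, with missing rows receiving the mean duration of
    the complete ones.  All-missing input is an error: there is no mean to
    impute from.  Complete records are returned unchanged.
    """
    out = records.copy()
    complete = out["table_on"].notna() & out["table_off"].notna()
    if not complete.any():
        raise TraceError("all records lack on/off-table times; nothing to impute from")
    durations = (
        (out.loc[complete, "table_off"] - out.loc[complete, "table_on"]).dt.total_seconds()
        / 60.0
    )
    out.loc[complete, "duration_minutes"] = durations
    out.loc[~complete, "duration_minutes"] = durations.mean()
    return out


def points_and_income(
    added_per_day: int,
    month_days: int,
    point_value_ntd: float = 0.847,
    ntd_per_usd: float = 30.0,
) -> IncomeProjection:
    """Monthly NHI points and USD income from extra daily examinations.

    Points are exams x tariff (6,500 without contrast, 11,500 with); USD is
    points x NTD-per-point / NTD-per-USD, rounded to whole dollars.
    """
    if added_per_day < 0:
        raise ValueError("added_per_day must be >= 0")
    if month_days < 1:
        raise ValueError("month_days must be >= 1")
    n = added_per_day * month_days
    pts_without = n * POINTS_WITHOUT_CONTRAST
    pts_with = n * POINTS_WITH_CONTRAST
    to_usd = point_value_ntd / ntd_per_usd
    return IncomeProjection(
        added_per_day=added_per_day,
        month_days=month_days,
        points_without_contrast=pts_without,
        points_with_contrast=pts_with,
        usd_without=int(round(pts_without * to_usd)),
        usd_with=int(round(pts_with * to_usd)),
    )


def percent_increase(added_total: int, baseline_total: int) -> float:
    """Percentage growth of the monthly exam count, to two decimals."""
    if baseline_total <= 0:
        raise ValueError("baseline_total must be > 0")
    return round(100.0 * added_total / baseline_total, 2)


def saved_minutes_per_day(
    prep_mean_before: float, prep_mean_after: float, exams_per_day: float
) -> float:
    """Daily preparation minutes reclaimed by a policy change.

    Negative output signals a policy that *increased* preparation time.
    """
    if exams_per_day <= 0:
        raise ValueError("exams_per_day must be > 0")
    return (prep_mean_before - prep_mean_after) * exams_per_day


def wait_time_reduction(
    baseline_trace: pd.DataFrame, proposed_trace: pd.DataFrame, coil: str
) -> dt.timedelta:
    """How much earlier the last exam of a coil finishes under the proposed
    (possibly augmented) schedule.

    Positive means the proposed run cleared the coil's waiting list sooner.
    The comparison is restricted to the requests present in both traces, so
    capacity-expansion runs are judged on the original booked population.
    """
    for name, trace in (("baseline", baseline_trace), ("proposed", proposed_trace)):
        if coil not in set(trace["coil"]):
            raise TraceError(f"coil {coil!r} absent from the {name} trace")
    shared = set(baseline_trace["request_id"]) & set(proposed_trace["request_id"])
    base = baseline_trace[
        (baseline_trace["coil"] == coil) & baseline_trace["request_id"].isin(shared)
    ]
    prop = proposed_trace[
        (proposed_trace["coil"] == coil) & proposed_trace["request_id"].isin(shared)
    ]
    if base.empty or prop.empty:
        raise TraceError(f"no shared {coil!r} exams between the traces")
    return (base["table_off"].max() - prop["table_off"].max()).to_pytimedelta()


def format_duration(delta: dt.timedelta) -> str:
    """Render a timedelta as the department's 'D d and H h' convention."""
    sign = "-" if delta < dt.timedelta(0) else ""
    delta = abs(delta)
    days = delta.days
    hours = round(delta.seconds / 3600)
    if hours == 24:
        days, hours = days + 1, 0
    if days and hours:
        return f"{sign}{days} d and {hours} h"
    if days:
        return f"{sign}{days} d"
    return f"{sign}{hours} h"
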