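"""Synthetic MRI exam-request logs.

The hospital's raw December-2016 examination log (one row per booked MRI
examination) is private.  This module generates request logs with the same
statistical structure: 11 coil types with per-coil median exam durations and
mean appointment-to-exam waits, a three-way patient-type mix
(outpatient / emergency-department / inpatient), a contrast-injection flag,
and an hourly demand calendar over a 16-hour service day that closes at
23:00.  It also reads and writes the logs as plain CSV.

All randomness flows through a single ``numpy.random.Generator`` seeded by
the caller, so equal ``(calibration, n_days, seed)`` triples produce
byte-identical CSV output.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "COIL_NAMES",
    "PATIENT_TYPES",
    "CoilProfile",
    "CalibrationTables",
    "ExamRequest",
    "CalibrationError",
    "LogFormatError",
    "default_calibration",
    "generate_requests",
    "read_requests",
    "write_requests",
    "save_calibration",
    "load_calibration",
    "REQUEST_COLUMNS",
]

#: Closed vocabulary of the 11 receiver-coil types used by the department.
COIL_NAMES = (
    "StdHead",
    "Card.",
    "8chHead",
    "Nuro.",
    "Breast",
    "Torso",
    "Spine",
    "LowExtre",
    "TorsoHead",
    "Knee",
    "Shoulder",
)

PATIENT_TYPES = ("outpatient", "emergency", "inpatient")

#: Fixed CSV column order for exam-request logs.
REQUEST_COLUMNS = (
    "request_id",
    "patient_type",
    "gender",
    "needs_contrast",
    "priority",
    "coil",
    "booking_datetime",
    "appointment_datetime",
)

# Per-coil (mean appointment-to-exam wait in days, median exam minutes).
# StdHead's 0.96 days corresponds to the department's quoted 23 hours.
_COIL_TABLE = {
    "StdHead": (0.96, 36.0),
    "Card.": (6.0, 99.0),
    "8chHead": (7.0, 28.0),
    "Nuro.": (8.0, 30.0),
    "Breast": (9.0, 46.0),
    "Torso": (10.0, 36.0),
    "Spine": (13.0, 25.0),
    "LowExtre": (15.0, 25.0),
    "TorsoHead": (21.0, 40.0),
    "Knee": (22.0, 27.0),
    "Shoulder": (22.0, 34.0),
}

# Monthly exam counts known per coil from the department's records (out of
# 2,447 exams); the remaining demand is spread uniformly over the other coils.
_KNOWN_MONTHLY_COUNTS = {
    "TorsoHead": 53,
    "Shoulder": 41,
    "8chHead": 398,
    "Torso": 1261,
}
_TOTAL_MONTHLY_EXAMS = 2447


class CalibrationError(ValueError):
    """Raised when calibration tables violate their invariants."""


class LogFormatError(ValueError):
    """Raised when a CSV exam-request log is malformed."""


@dataclass(frozen=True)
class CoilProfile:
    """Demand and service profile of one coil type."""

    coil_name: str
    median_exam_minutes: float
    mean_wait_days: float
    demand_share: float

    def __post_init__(self) -> None:
        if self.coil_name not in COIL_NAMES:
            raise CalibrationError(f"unknown coil name {self.coil_name!r}")
        if self.median_exam_minutes <= 0:
            raise CalibrationError(
                f"{self.coil_name}: median_exam_minutes must be > 0"
            )
        if self.mean_wait_days < 0:
            raise CalibrationError(f"{self.coil_name}: mean_wait_days must be >= 0")


@dataclass
class CalibrationTables:
    """Everything the generator needs to emulate one month of demand.

    ``arrivals_per_hour`` maps ``(weekday, hour)`` to the expected number of
    appointment arrivals in that hour, with ``weekday`` in 0..6 (Monday = 0,
    matching :meth:`datetime.date.weekday`).  The service day spans exactly
    16 hours and ends at 23:00; rates outside it must be absent or zero.
    """

    coil_profiles: dict[str, CoilProfile]
    patient_type_shares: dict[str, float]
    exam_time_mean_sd: tuple[float, float]
    prep_time_mean_sd: tuple[float, float]
    contrast_probability: float
    arrivals_per_hour: dict[tuple[int, int], float]
    service_day_start: dt.time = dt.time(7, 0)
    service_day_end: dt.time = dt.time(23, 0)
    female_share: float = 0.5
    daily_coil_changes_mean_sd: tuple[float, float] = (43.35, 6.05)
    utilization_pct: dict[str, float] = field(
        default_factory=lambda: {"A": 85.06, "B": 85.48, "C": 85.20, "D": 81.30}
    )

    def validate(self) -> None:
        if set(self.coil_profiles) != set(COIL_NAMES):
            raise CalibrationError("coil_profiles must cover exactly the 11 coil types")
        share_sum = sum(p.demand_share for p in self.coil_profiles.values())
        if abs(share_sum - 1.0) > 1e-9:
            raise CalibrationError(f"coil demand shares sum to {share_sum}, not 1")
        if set(self.patient_type_shares) != set(PATIENT_TYPES):
            raise CalibrationError("patient_type_shares must key outpatient/emergency/inpatient")
        tsum = sum(self.patient_type_shares.values())
        if abs(tsum - 1.0) > 1e-9:
            raise CalibrationError(f"patient type shares sum to {tsum}, not 1")
        start = dt.datetime.combine(dt.date(2000, 1, 3), self.service_day_start)
        end = dt.datetime.combine(dt.date(2000, 1, 3), self.service_day_end)
        if (end - start) != dt.timedelta(hours=16) or self.service_day_end != dt.time(23, 0):
            raise CalibrationError("service day must span 16 hours and end at 23:00")
        if not 0.0 <= self.contrast_probability <= 1.0:
            raise CalibrationError("contrast_probability must lie in [0, 1]")
        lo, hi = self.service_day_start.hour, self.service_day_end.hour
        for (wd, hour), rate in self.arrivals_per_hour.items():
            if rate < 0:
                raise CalibrationError(f"negative arrival rate at weekday {wd} hour {hour}")
            if rate > 0 and not lo <= hour < hi:
                raise CalibrationError(
                    f"nonzero arrival rate outside the service day: weekday {wd} hour {hour}"
                )

    @property
    def service_hours(self) -> range:
        return range(self.service_day_start.hour, self.service_day_end.hour)

    # -- (de)serialisation ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "coil_profiles": {
                name: {
                    "median_exam_minutes": p.median_exam_minutes,
                    "mean_wait_days": p.mean_wait_days,
                    "demand_share": p.demand_share,
                }
                for name, p in self.coil_profiles.items()
            },
            "patient_type_shares": dict(self.patient_type_shares),
            "exam_time_mean_sd": list(self.exam_time_mean_sd),
            "prep_time_mean_sd": list(self.prep_time_mean_sd),
            "contrast_probability": self.contrast_probability,
            "arrivals_per_hour": {
                f"{wd},{hour}": rate
                for (wd, hour), rate in sorted(self.arrivals_per_hour.items())
            },
            "service_day_start": self.service_day_start.isoformat(),
            "service_day_end": self.service_day_end.isoformat(),
            "female_share": self.female_share,
            "daily_coil_changes_mean_sd": list(self.daily_coil_changes_mean_sd),
            "utilization_pct": dict(self.utilization_pct),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationTables":
        profiles = {
            name: CoilProfile(coil_name=name, **vals)
            for name, vals in d["coil_profiles"].items()
        }
        arrivals = {}
        for key, rate in d["arrivals_per_hour"].items():
            wd, hour = (int(x) for x in key.split(","))
            arrivals[(wd, hour)] = float(rate)
        calib = cls(
            coil_profiles=profiles,
            patient_type_shares={k: float(v) for k, v in d["patient_type_shares"].items()},
            exam_time_mean_sd=tuple(d["exam_time_mean_sd"]),
            prep_time_mean_sd=tuple(d["prep_time_mean_sd"]),
            contrast_probability=float(d["contrast_probability"]),
            arrivals_per_hour=arrivals,
            service_day_start=dt.time.fromisoformat(d["service_day_start"]),
            service_day_end=dt.time.fromisoformat(d["service_day_end"]),
            female_share=float(d.get("female_share", 0.5)),
            daily_coil_changes_mean_sd=tuple(d.get("daily_coil_changes_mean_sd", (43.35, 6.05))),
            utilization_pct=dict(d.get("utilization_pct", {})),
        )
        calib.validate()
        return calib


@dataclass(frozen=True)
class ExamRequest:
    """One booked MRI examination."""

    request_id: str
    patient_type: str
    gender: str
    needs_contrast: bool
    priority: bool
    coil: str
    booking_datetime: dt.datetime
    appointment_datetime: dt.datetime

    def __post_init__(self) -> None:
        if self.coil not in COIL_NAMES:
            raise LogFormatError(f"unknown coil {self.coil!r}")
        if self.patient_type not in PATIENT_TYPES:
            raise LogFormatError(f"unknown patient type {self.patient_type!r}")
        if self.appointment_datetime < self.booking_datetime:
            raise LogFormatError(
                f"{self.request_id}: appointment precedes booking"
            )
        if self.priority != (self.patient_type == "emergency"):
            raise LogFormatError(
                f"{self.request_id}: priority flag must mirror emergency status"
            )


def default_calibration() -> CalibrationTables:
    """Calibration tables populated with the department's published figures.

    Patient-type shares are 74.34 / 5.93 / 19.74 % (outpatient / emergency /
    inpatient).  Per-coil demand shares use the known monthly exam counts for
    the four coils with published volumes and spread the remaining demand
    uniformly over the other seven.  The demand calendar books 79 exams per
    day on average (2,449 over a 31-day month), uniformly over the 16 service
    hours.
    """
    known_share = {
        name: count / _TOTAL_MONTHLY_EXAMS
        for name, count in _KNOWN_MONTHLY_COUNTS.items()
    }
    remaining = 1.0 - sum(known_share.values())
    n_other = len(COIL_NAMES) - len(known_share)
    profiles = {}
    for name in COIL_NAMES:
        wait, median = _COIL_TABLE[name]
        share = known_share.get(name, remaining / n_other)
        profiles[name] = CoilProfile(
            coil_name=name,
            median_exam_minutes=median,
            mean_wait_days=wait,
            demand_share=share,
        )
    # re-normalise away float crumbs so shares sum to 1 exactly
    total = sum(p.demand_share for p in profiles.values())
    profiles = {
        name: replace(p, demand_share=p.demand_share / total)
        for name, p in profiles.items()
    }

    per_hour = (2449 / 31) / 16.0  # 79 exams/day over 16 service hours
    arrivals = {(wd, hour): per_hour for wd in range(7) for hour in range(7, 23)}

    # the department's published shares (74.34/5.93/19.74%) carry a rounding
    # crumb summing to 1.0001; normalise so the partition is exact
    type_shares = {"outpatient": 0.7434, "emergency": 0.0593, "inpatient": 0.1974}
    type_total = sum(type_shares.values())
    calib = CalibrationTables(
        coil_profiles=profiles,
        patient_type_shares={k: v / type_total for k, v in type_shares.items()},
        exam_time_mean_sd=(33.03, 1.97),
        prep_time_mean_sd=(5.07, 0.63),
        contrast_probability=0.4,
        arrivals_per_hour=arrivals,
    )
    calib.validate()
    return calib


def generate_requests(
    calib: CalibrationTables,
    n_days: int,
    seed: int,
    start_date: dt.date = dt.date(2016, 12, 1),
    daily_total: int | None = None,
) -> list[ExamRequest]:
    """Draw a month of exam requests from the calibration tables.

    Parameters
    ----------
    calib
        Validated calibration tables; a calibration whose shares do not sum
        to 1 is rejected.
    n_days
        Number of consecutive service days starting at ``start_date``.
    seed
        Seed for the single random stream; equal inputs give equal output.
    start_date
        First service day (default December 1, 2016).
    daily_total
        If given, book exactly this many exams per day (spread over the
        hourly calendar proportionally to its rates); otherwise hourly counts
        are Poisson with the calendar's rates.

    Appointment times are drawn from the hourly demand calendar; the booking
    time is the appointment minus an exponentially distributed wait with the
    coil's mean appointment-to-exam wait, so every appointment lies inside
    the service day and never precedes its booking.
    """
    if n_days < 0:
        raise ValueError("n_days must be >= 0")
    calib.validate()
    rng = np.random.default_rng(seed)

    coil_names = list(COIL_NAMES)
    coil_p = np.array([calib.coil_profiles[c].demand_share for c in coil_names])
    type_names = list(PATIENT_TYPES)
    type_p = np.array([calib.patient_type_shares[t] for t in type_names])

    requests: list[ExamRequest] = []
    serial = 0
    for day_idx in range(n_days):
        day = start_date + dt.timedelta(days=day_idx)
        wd = day.weekday()
        hours = list(calib.service_hours)
        rates = np.array([calib.arrivals_per_hour.get((wd, h), 0.0) for h in hours])
        if daily_total is None:
            counts = rng.poisson(rates)
        else:
            if rates.sum() <= 0:
                counts = np.zeros(len(hours), dtype=int)
            else:
                counts = rng.multinomial(daily_total, rates / rates.sum())
        day_requests = []
        for hour, count in zip(hours, counts):
            for _ in range(int(count)):
                minute_offset = rng.uniform(0.0, 60.0)
                appt = dt.datetime.combine(day, dt.time(hour, 0)) + dt.timedelta(
                    minutes=float(minute_offset)
                )
                coil = coil_names[rng.choice(len(coil_names), p=coil_p)]
                ptype = type_names[rng.choice(len(type_names), p=type_p)]
                gender = "female" if rng.random() < calib.female_share else "male"
                contrast = bool(rng.random() < calib.contrast_probability)
                wait_days = rng.exponential(calib.coil_profiles[coil].mean_wait_days)
                booking = appt - dt.timedelta(days=float(wait_days))
                day_requests.append((appt, coil, ptype, gender, contrast, booking))
        day_requests.sort(key=lambda r: r[0])
        for appt, coil, ptype, gender, contrast, booking in day_requests:
            serial += 1
            requests.append(
                ExamRequest(
                    request_id=f"R{serial:06d}",
                    patient_type=ptype,
                    gender=gender,
                    needs_contrast=contrast,
                    priority=(ptype == "emergency"),
                    coil=coil,
                    booking_datetime=booking.replace(microsecond=0),
                    appointment_datetime=appt.replace(microsecond=0),
                )
            )
    return requests


def write_requests(requests: list[ExamRequest], path) -> None:
    """Write an exam-request log as CSV with the documented column order."""
    rows = [
        {
            "request_id": r.request_id,
            "patient_type": r.patient_type,
            "gender": r.gender,
            "needs_contrast": int(r.needs_contrast),
            "priority": int(r.priority),
            "coil": r.coil,
            "booking_datetime": r.booking_datetime.isoformat(),
            "appointment_datetime": r.appointment_datetime.isoformat(),
        }
        for r in requests
    ]
    df = pd.DataFrame(rows, columns=list(REQUEST_COLUMNS))
    df.to_csv(path, index=False, lineterminator="\n")


def read_requests(path) -> list[ExamRequest]:
    """Read an exam-request CSV; ``write_requests`` then ``read_requests``
    is the identity on the request list."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUEST_COLUMNS if c not in df.columns]
    if missing:
        raise LogFormatError(f"missing column(s): {', '.join(missing)}")
    requests = []
    for idx, row in df.iterrows():
        coil = row["coil"]
        if coil not in COIL_NAMES:
            raise LogFormatError(f"row {idx}: unknown coil {coil!r}")
        try:
            booking = dt.datetime.fromisoformat(row["booking_datetime"])
            appt = dt.datetime.fromisoformat(row["appointment_datetime"])
        except ValueError as exc:
            raise LogFormatError(f"row {idx}: unparseable timestamp ({exc})") from exc
        requests.append(
            ExamRequest(
                request_id=row["request_id"],
                patient_type=row["patient_type"],
                gender=row["gender"],
                needs_contrast=bool(int(row["needs_contrast"])),
                priority=bool(int(row["priority"])),
                coil=coil,
                booking_datetime=booking,
                appointment_datetime=appt,
            )
        )
    return requests


def save_calibration(calib: CalibrationTables, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(calib.to_dict(), fh, sort_keys=True)


def load_calibration(path) -> CalibrationTables:
    with open(path) as fh:
        return CalibrationTables.from_dict(yaml.safe_load(fh))
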