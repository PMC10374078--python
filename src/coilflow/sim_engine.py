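"""Discrete-event execution of an MRI examination schedule.

The engine walks the five-station patient flow — registration, dressing,
optional IV contrast setup, waiting, examination (one or two scan segments),
optional IV removal — for every scheduled request, with scanners as
contended agents: a scanner runs its day's slots in order, carries a mounted
coil (by default across days), and pays an extra changeover when the next
exam needs a different coil.  The output is a timestamped event trace with
one row per examination.

Service-time model
------------------
* Ancillary stations (registration, dressing, IV setup/removal) are
  triangular around their configured modes with ±50% spread; the hospital
  log does not record them, so these are operational rules of thumb.
* Examination preparation is ``base_setup + coil_change`` minutes, the
  changeover term charged iff the required coil differs from the mounted
  one (a bare scanner counts as a change).  The two components are
  identified from two published operating points (mean prep time at two
  coil-change rates) by :func:`calibrate_prep_components`.
* Scan durations are lognormal, anchored at each coil's median, scaled so
  the expected population mean matches the calibration target; contrast
  exams run two segments whose total is the coil draw times a configurable
  factor.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scheduling import SCANNERS, CompatibilityMatrix, Schedule, default_compatibility
from .synthetic_logs import CalibrationTables, ExamRequest

__all__ = [
    "ServiceTimeConfig",
    "ScannerState",
    "SimulationError",
    "TRACE_COLUMNS",
    "calibrate_prep_components",
    "default_service_config",
    "prep_time",
    "select_scanner",
    "run_simulation",
    "write_trace",
    "read_trace",
]


#: Column order of the event-trace table.
TRACE_COLUMNS = (
    "request_id",
    "scanner_id",
    "day",
    "coil",
    "patient_type",
    "needs_contrast",
    "appointment",
    "booking",
    "prep_start",
    "table_on",
    "table_off",
    "coil_changed",
)

# Published operating points (mean prep minutes, coil changes/day) used to
# identify the prep-time components; 79 exams/day converts changes to a rate.
_PREP_POINT_BASELINE = (5.27, 40.38)
_PREP_POINT_PROPOSED = (4.04, 13.04)
_EXAMS_PER_DAY = 79.0


class SimulationError(RuntimeError):
    """Raised for inconsistent schedules or configurations."""


@dataclass
class ScannerState:
    """Mutable state of one scanner agent."""

    scanner_id: str
    usable_coils: frozenset[str]
    mounted_coil: str | None = None
    busy_until: dt.datetime | None = None

    def is_idle(self, now: dt.datetime) -> bool:
        return self.busy_until is None or self.busy_until <= now


@dataclass
class ServiceTimeConfig:
    """Tunable service times, all in minutes."""

    base_setup_minutes: float
    coil_change_minutes: float
    registration_minutes: float = 3.0
    dressing_minutes: float = 5.0
    iv_setup_minutes: float = 5.0
    iv_removal_minutes: float = 3.0
    ancillary_spread: float = 0.5  # triangular ±50% around the mode
    exam_lognorm_sigma: float = 0.25
    contrast_scan_factor: float = 1.1
    exam_time_scale: float = 1.0
    carry_coil_overnight: bool = True
    coil_median_minutes: dict[str, float] = field(default_factory=dict)

    def ancillary(self, rng: np.random.Generator, mode: float) -> float:
        lo = mode * (1.0 - self.ancillary_spread)
        hi = mode * (1.0 + self.ancillary_spread)
        return float(rng.triangular(lo, mode, hi)) if hi > lo else mode


def calibrate_prep_components(
    prep_mean_1: float,
    change_rate_1: float,
    prep_mean_2: float,
    change_rate_2: float,
) -> tuple[float, float]:
    """Identify (base setup, coil changeover) minutes from two operating points.

    Each observed mean preparation time is ``base + rate * change`` where
    ``rate`` is coil changes per exam; two distinct rates give a 2x2 linear
    system.  Equal rates leave the system singular.
    """
    if math.isclose(change_rate_1, change_rate_2):
        raise ValueError("change rates are equal: the 2x2 system is singular")
    change = (prep_mean_1 - prep_mean_2) / (change_rate_1 - change_rate_2)
    base = prep_mean_1 - change_rate_1 * change
    return base, change


def default_service_config(calib: CalibrationTables) -> ServiceTimeConfig:
    """Service times anchored to the published department figures.

    Prep components come from the two published (mean prep, change rate)
    operating points; the exam-time scale is solved so the expected
    population mean scan duration equals the calibration's mean exam time.
    """
    base, change = calibrate_prep_components(
        _PREP_POINT_BASELINE[0],
        _PREP_POINT_BASELINE[1] / _EXAMS_PER_DAY,
        _PREP_POINT_PROPOSED[0],
        _PREP_POINT_PROPOSED[1] / _EXAMS_PER_DAY,
    )
    cfg = ServiceTimeConfig(
        base_setup_minutes=base,
        coil_change_minutes=change,
        coil_median_minutes={
            name: p.median_exam_minutes for name, p in calib.coil_profiles.items()
        },
    )
    weighted_median = sum(
        p.demand_share * p.median_exam_minutes for p in calib.coil_profiles.values()
    )
    lognorm_mean_factor = math.exp(cfg.exam_lognorm_sigma**2 / 2.0)
    p_c = calib.contrast_probability
    contrast_adjust = (1.0 - p_c) + p_c * cfg.contrast_scan_factor
    target_mean = calib.exam_time_mean_sd[0]
    cfg.exam_time_scale = target_mean / (
        weighted_median * lognorm_mean_factor * contrast_adjust
    )
    return cfg


def prep_time(
    scanner_state: ScannerState, request: ExamRequest, config: ServiceTimeConfig
) -> float:
    """Scanner preparation minutes for a request: base setup plus the
    changeover iff the mounted coil differs (a bare scanner always changes)."""
    minutes = config.base_setup_minutes
    if scanner_state.mounted_coil != request.coil:
        minutes += config.coil_change_minutes
    return minutes


def select_scanner(
    request: ExamRequest,
    scanner_states: dict[str, ScannerState],
    scheduled_scanner: str | None = None,
    now: dt.datetime | None = None,
) -> str:
    """Pick the scanner to serve a request.

    The scheduled scanner wins when it is compatible and idle at ``now``;
    otherwise the compatible scanner that frees up earliest (idle scanners
    first, ties broken by scanner id).  A coil no scanner can mount is a
    configuration error.
    """
    compatible = [
        s for s in sorted(scanner_states) if request.coil in scanner_states[s].usable_coils
    ]
    if not compatible:
        raise SimulationError(f"no scanner can mount coil {request.coil!r}")
    if scheduled_scanner in compatible:
        state = scanner_states[scheduled_scanner]
        if now is None or state.is_idle(now):
            return scheduled_scanner
    def free_at(s: str) -> dt.datetime:
        b = scanner_states[s].busy_until
        if b is None or (now is not None and b <= now):
            return dt.datetime.min
        return b

    return min(compatible, key=lambda s: (free_at(s), s))


def run_simulation(
    schedule: Schedule,
    requests,
    config: ServiceTimeConfig,
    compat: CompatibilityMatrix | None = None,
    seed: int = 0,
    service_day_start: dt.time = dt.time(7, 0),
) -> pd.DataFrame:
    """Execute a schedule and return the event trace.

    Every scheduled request yields exactly one exam row; exams on a scanner
    run in slot order and never overlap; the ``coil_changed`` flag records
    each mounted-coil transition.  Patients take their scanner-day's booked
    appointment times in slot order (a reordering policy swaps patients
    between the day's appointment slots rather than inventing new arrival
    times), then pass registration, dressing and — for contrast exams — IV
    setup before the scanner is prepared.  Reproducible under a fixed seed.
    """
    compat = compat or default_compatibility()
    req_lookup = {r.request_id: r for r in requests}
    for slot in schedule.slots:
        if slot.request_id not in req_lookup:
            raise SimulationError(f"schedule references unknown request_id {slot.request_id!r}")

    rng = np.random.default_rng(seed)
    states = {s: ScannerState(s, compat.usable.get(s, frozenset())) for s in SCANNERS}
    rows = []
    by_day = schedule.by_scanner_day()
    for (scanner, day) in sorted(by_day, key=lambda k: (k[1], k[0])):
        state = states[scanner]
        if not config.carry_coil_overnight:
            state.mounted_coil = None
        slots = by_day[(scanner, day)]
        day_open = dt.datetime.combine(day, service_day_start)
        # patients swap appointment slots under a reordering policy
        arrival_times = sorted(
            req_lookup[s.request_id].appointment_datetime for s in slots
        )
        free_at = day_open
        for slot, arrival in zip(slots, arrival_times):
            req = req_lookup[slot.request_id]
            if req.coil not in state.usable_coils:
                raise SimulationError(
                    f"request {req.request_id} needs coil {req.coil!r}, "
                    f"which scanner {scanner} cannot mount"
                )
            ready = arrival
            ready += dt.timedelta(minutes=config.ancillary(rng, config.registration_minutes))
            ready += dt.timedelta(minutes=config.ancillary(rng, config.dressing_minutes))
            if req.needs_contrast:
                ready += dt.timedelta(minutes=config.ancillary(rng, config.iv_setup_minutes))
            prep_start = max(free_at, ready, day_open)
            changed = state.mounted_coil != req.coil
            prep = prep_time(state, req, config)
            table_on = prep_start + dt.timedelta(minutes=prep)
            scan = _draw_scan_minutes(rng, req, config)
            table_off = table_on + dt.timedelta(minutes=scan)
            state.mounted_coil = req.coil
            state.busy_until = table_off
            free_at = table_off
            rows.append(
                {
                    "request_id": req.request_id,
                    "scanner_id": scanner,
                    "day": day,
                    "coil": req.coil,
                    "patient_type": req.patient_type,
                    "needs_contrast": req.needs_contrast,
                    "appointment": arrival,
                    "booking": req.booking_datetime,
                    "prep_start": prep_start,
                    "table_on": table_on,
                    "table_off": table_off,
                    "coil_changed": changed,
                }
            )
    trace = pd.DataFrame(rows, columns=list(TRACE_COLUMNS))
    if not trace.empty:
        for col in ("appointment", "booking", "prep_start", "table_on", "table_off"):
            trace[col] = pd.to_datetime(trace[col])
    return trace


def _draw_scan_minutes(rng, req, config) -> float:
    """Lognormal scan duration anchored at the coil's median; contrast exams
    run two segments totalling the draw times the contrast factor."""
    median = config.coil_median_minutes.get(req.coil)
    if median is None:
        raise SimulationError(f"no median exam duration configured for coil {req.coil!r}")
    draw = median * math.exp(config.exam_lognorm_sigma * rng.standard_normal())
    minutes = config.exam_time_scale * draw
    if req.needs_contrast:
        minutes *= config.contrast_scan_factor
    return minutes


def write_trace(trace: pd.DataFrame, path) -> None:
    out = trace.copy()
    for col in ("appointment", "booking", "prep_start", "table_on", "table_off"):
        out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    out.to_csv(path, index=False, lineterminator="\n")


def read_trace(path) -> pd.DataFrame:
    trace = pd.read_csv(path)
    for col in ("appointment", "booking", "prep_start", "table_on", "table_off"):
        trace[col] = pd.to_datetime(trace[col])
    trace["day"] = pd.to_datetime(trace["day"]).dt.date
    return trace
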