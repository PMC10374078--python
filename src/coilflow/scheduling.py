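"""Scheduling policies for the MRI department.

Two policies turn a month of booked exam requests into ordered per-scanner,
per-session sequences:

* **baseline** — requests run in appointment order; each is routed to a
  scanner by sampling the coil's routing probabilities (each scanner can
  mount only a subset of the 11 coil types).
* **proposed** — the week is banded into three groups (Sunday–Monday,
  Tuesday–Wednesday, Thursday–Saturday) and, within each scanner-day,
  same-coil exams are regrouped into contiguous blocks so the scanner's
  mounted coil changes as rarely as possible.  The reordering is a
  permutation of the baseline assignment: no request is lost, duplicated or
  moved to an incompatible scanner.

The module also provides the static coil-change counter used to audit both
policies and the phase-2 augmentation that converts saved preparation
minutes into extra daily examinations.
"""

from __future__ import annotations

import datetime as dt
import itertools
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_logs import COIL_NAMES, CalibrationTables, ExamRequest

__all__ = [
    "SCANNERS",
    "SESSIONS",
    "CompatibilityMatrix",
    "ScheduleSlot",
    "Schedule",
    "CompatibilityError",
    "InfeasibleAugmentationError",
    "default_compatibility",
    "weekday_group",
    "session_of",
    "count_coil_changes",
    "baseline_schedule",
    "proposed_schedule",
    "choose_added_coils",
    "augment_schedule",
    "write_schedule",
]

SCANNERS = ("A", "B", "C", "D")
SESSIONS = ("morning", "afternoon", "evening")

#: Session clock bounds within the 07:00–23:00 service day.
_SESSION_BOUNDS = {"morning": (7, 12), "afternoon": (12, 17), "evening": (17, 23)}

#: Coils the phase-2 augmentation may add, in the department's order.
DEFAULT_AUGMENT_COILS = ("TorsoHead", "Shoulder", "8chHead", "Torso")


class CompatibilityError(ValueError):
    """Raised when a request's coil cannot be routed to any scanner."""


class InfeasibleAugmentationError(ValueError):
    """Raised when no coil combination fits within the saved minutes."""


@dataclass(frozen=True)
class CompatibilityMatrix:
    """Scanner/coil compatibility and routing probabilities.

    ``usable`` maps each scanner to the set of coils it can mount; ``routing``
    maps each coil to its per-scanner routing probabilities.  A coil's
    probability must be zero on any scanner not listing it, and each coil's
    probabilities sum to 1.
    """

    usable: dict[str, frozenset[str]]
    routing: dict[str, dict[str, float]]

    def validate(self) -> None:
        for scanner in self.usable:
            if scanner not in SCANNERS:
                raise CompatibilityError(f"unknown scanner {scanner!r}")
        for coil, row in self.routing.items():
            if coil not in COIL_NAMES:
                raise CompatibilityError(f"unknown coil {coil!r}")
            total = sum(row.values())
            if total <= 0:
                raise CompatibilityError(f"coil {coil!r} has an all-zero routing row")
            if abs(total - 1.0) > 1e-9:
                raise CompatibilityError(
                    f"coil {coil!r} routing probabilities sum to {total}, not 1"
                )
            for scanner, p in row.items():
                if p > 0 and coil not in self.usable.get(scanner, frozenset()):
                    raise CompatibilityError(
                        f"coil {coil!r} routed to scanner {scanner} which cannot mount it"
                    )

    def scanners_for(self, coil: str) -> list[str]:
        return [s for s in SCANNERS if coil in self.usable.get(s, frozenset())]


def default_compatibility() -> CompatibilityMatrix:
    """Default scanner/coil matrix for the four-scanner department.

    The two hard constraints are that the cardiac coil mounts only on
    scanner C (100% routing) and the standard head coil routes 3% / 97% to
    scanners C and D.  Usable-set sizes are A=8, B=9, C=10, D=7.  The
    remaining routing rows split demand equally over the scanners that can
    mount the coil; the full matrix is a configuration input.
    """
    usable = {
        "A": frozenset(
            {"8chHead", "Nuro.", "Breast", "Torso", "Spine", "LowExtre", "TorsoHead", "Shoulder"}
        ),
        "B": frozenset(
            {"8chHead", "Nuro.", "Breast", "Torso", "Spine", "LowExtre", "TorsoHead", "Knee", "Shoulder"}
        ),
        "C": frozenset(set(COIL_NAMES) - {"Breast"}),
        "D": frozenset({"StdHead", "8chHead", "Nuro.", "Torso", "Spine", "Knee", "Shoulder"}),
    }
    routing: dict[str, dict[str, float]] = {}
    for coil in COIL_NAMES:
        if coil == "Card.":
            routing[coil] = {"C": 1.0}
        elif coil == "StdHead":
            routing[coil] = {"C": 0.03, "D": 0.97}
        else:
            hosts = [s for s in SCANNERS if coil in usable[s]]
            routing[coil] = {s: 1.0 / len(hosts) for s in hosts}
    matrix = CompatibilityMatrix(usable=usable, routing=routing)
    matrix.validate()
    assert tuple(len(usable[s]) for s in SCANNERS) == (8, 9, 10, 7)
    return matrix


@dataclass(frozen=True)
class ScheduleSlot:
    scanner_id: str
    day: dt.date
    session: str
    slot_index: int  # order within the scanner-day
    request_id: str
    coil: str


@dataclass
class Schedule:
    """Ordered per-scanner-day exam sequences produced by a policy."""

    slots: list[ScheduleSlot]
    policy_name: str

    def by_scanner_day(self) -> dict[tuple[str, dt.date], list[ScheduleSlot]]:
        grouped: dict[tuple[str, dt.date], list[ScheduleSlot]] = defaultdict(list)
        for slot in self.slots:
            grouped[(slot.scanner_id, slot.day)].append(slot)
        for key in grouped:
            grouped[key].sort(key=lambda s: s.slot_index)
        return dict(grouped)

    def request_ids(self) -> list[str]:
        return [s.request_id for s in self.slots]


def weekday_group(day: dt.date) -> str:
    """Weekday band of the proposed policy: Sunday–Monday = G1,
    Tuesday–Wednesday = G2, Thursday–Saturday = G3."""
    wd = day.weekday()  # Monday = 0 .. Sunday = 6
    if wd in (6, 0):
        return "G1"
    if wd in (1, 2):
        return "G2"
    return "G3"


def session_of(when: dt.datetime | dt.time) -> str:
    """Session (morning/afternoon/evening) containing a clock time."""
    hour = when.hour
    for name, (lo, hi) in _SESSION_BOUNDS.items():
        if lo <= hour < hi:
            return name
    # outside the service day: clamp to the nearest session
    return "morning" if hour < 7 else "evening"


def count_coil_changes(coils, initial_mounted_coil=None) -> int:
    """Number of coil swaps needed to run ``coils`` in order.

    The first exam counts as a change iff its coil differs from
    ``initial_mounted_coil`` (``None`` means no coil mounted, so any first
    exam is a change).
    """
    changes = 0
    mounted = initial_mounted_coil
    for coil in coils:
        if coil != mounted:
            changes += 1
            mounted = coil
    return changes


def _route(requests, compat: CompatibilityMatrix, seed: int) -> dict[str, str]:
    """Sample a scanner for every request from its coil's routing row."""
    compat.validate()
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for req in sorted(requests, key=lambda r: (r.appointment_datetime, r.request_id)):
        row = compat.routing.get(req.coil)
        if not row:
            raise CompatibilityError(f"coil {req.coil!r} has no routing row")
        scanners = sorted(row)
        probs = np.array([row[s] for s in scanners])
        assignment[req.request_id] = scanners[rng.choice(len(scanners), p=probs / probs.sum())]
    return assignment


def _build_slots(day_orders, policy_name, req_lookup) -> Schedule:
    """Materialise per-scanner-day request orderings into slots."""
    slots = []
    for (scanner, day), ordered_ids in sorted(day_orders.items()):
        for idx, rid in enumerate(ordered_ids):
            req = req_lookup[rid]
            slots.append(
                ScheduleSlot(
                    scanner_id=scanner,
                    day=day,
                    session=session_of(req.appointment_datetime),
                    slot_index=idx,
                    request_id=rid,
                    coil=req.coil,
                )
            )
    slots.sort(key=lambda s: (s.day, s.scanner_id, s.slot_index))
    return Schedule(slots=slots, policy_name=policy_name)


def baseline_schedule(requests, compat: CompatibilityMatrix, seed: int) -> Schedule:
    """As-booked policy: appointment order on a probabilistically routed scanner."""
    req_lookup = {r.request_id: r for r in requests}
    assignment = _route(requests, compat, seed)
    day_orders: dict[tuple[str, dt.date], list[str]] = defaultdict(list)
    for req in sorted(requests, key=lambda r: (r.appointment_datetime, r.request_id)):
        day_orders[(assignment[req.request_id], req.appointment_datetime.date())].append(
            req.request_id
        )
    return _build_slots(day_orders, "baseline", req_lookup)


def _group_day(ordered_ids, req_lookup, mounted: str | None) -> list[str]:
    """Reorder one scanner-day so same-coil exams form contiguous blocks.

    Two anchors bound the block order: the block matching the coil mounted
    at day start runs first (so the first exam triggers no change), and the
    block of the day's *original* closing coil runs last, so the scanner
    ends the day in the same state as under the as-booked schedule.  Keeping
    the closing state untouched decouples the days: regrouping one day can
    never make a later day worse, and each day's change count never exceeds
    the as-booked count.  Middle blocks run by descending size, ties broken
    by first appearance.  Within a block, emergency patients move to the
    front; otherwise booking order is preserved.
    """
    blocks: dict[str, list[str]] = {}
    for rid in ordered_ids:
        blocks.setdefault(req_lookup[rid].coil, []).append(rid)
    if not blocks:
        return []
    closing = req_lookup[ordered_ids[-1]].coil
    first_seen = {coil: i for i, coil in enumerate(blocks)}
    d = len(blocks)

    def block_key(coil: str):
        is_first = coil == mounted and (mounted != closing or d == 1)
        is_last = d > 1 and coil == closing
        return (not is_first, is_last, -len(blocks[coil]), first_seen[coil])

    out: list[str] = []
    for coil in sorted(blocks, key=block_key):
        members = blocks[coil]
        out.extend([r for r in members if req_lookup[r].priority])
        out.extend([r for r in members if not req_lookup[r].priority])
    return out


def proposed_schedule(requests, compat: CompatibilityMatrix, seed: int = 0) -> Schedule:
    """Coil-grouped policy.

    Scanner routing is identical to the baseline under the same seed (the
    two arms are paired); within each scanner-day the sequence is regrouped
    into contiguous same-coil blocks, with the mounted coil carried across
    days so consecutive days of a weekday band chain their blocks.
    """
    baseline = baseline_schedule(requests, compat, seed)
    req_lookup = {r.request_id: r for r in requests}
    day_orders: dict[tuple[str, dt.date], list[str]] = {}
    by_day = baseline.by_scanner_day()
    mounted: dict[str, str | None] = {s: None for s in SCANNERS}
    for (scanner, day) in sorted(by_day, key=lambda k: (k[1], k[0])):
        ordered = [s.request_id for s in by_day[(scanner, day)]]
        grouped = _group_day(ordered, req_lookup, mounted[scanner])
        day_orders[(scanner, day)] = grouped
        if grouped:
            mounted[scanner] = req_lookup[grouped[-1]].coil
    return _build_slots(day_orders, "proposed", req_lookup)


def choose_added_coils(
    k: int,
    saved_minutes: float,
    calib: CalibrationTables,
    candidates=DEFAULT_AUGMENT_COILS,
) -> tuple[str, ...]:
    """Pick the multiset of ``k`` candidate coils whose median exam durations
    fit in the saved minutes, maximising the reclaimed exam time.

    Raises :class:`InfeasibleAugmentationError` when no combination fits.
    """
    if k == 0:
        return ()
    medians = {c: calib.coil_profiles[c].median_exam_minutes for c in candidates}
    best: tuple[str, ...] | None = None
    best_total = -1.0
    for combo in itertools.combinations_with_replacement(
        sorted(candidates, key=lambda c: -medians[c]), k
    ):
        total = sum(medians[c] for c in combo)
        if total <= saved_minutes + 1e-9 and total > best_total:
            best, best_total = combo, total
    if best is None:
        raise InfeasibleAugmentationError(
            f"no combination of {k} coil(s) from {tuple(candidates)} fits "
            f"within {saved_minutes:.2f} saved minutes/day"
        )
    return best


def augment_schedule(
    schedule: Schedule,
    requests,
    k_per_day: int,
    saved_minutes_per_day: float,
    calib: CalibrationTables,
    compat: CompatibilityMatrix | None = None,
    candidates=DEFAULT_AUGMENT_COILS,
) -> tuple[Schedule, list[ExamRequest]]:
    """Append ``k_per_day`` extra exams per day to a proposed schedule.

    The added coils are chosen so the sum of their median exam durations
    fits within the saved preparation minutes; each extra exam is placed
    adjacent to an existing block of the same coil (or at the end of the
    least-loaded compatible scanner-day when the coil does not run that day).
    Returns the augmented schedule together with the full request list
    including the synthesised extra requests.  ``k_per_day == 0`` returns the
    inputs unchanged.
    """
    if not 0 <= k_per_day <= 3:
        raise ValueError("k_per_day must be in 0..3")
    if saved_minutes_per_day < 0:
        raise ValueError("saved_minutes_per_day must be >= 0")
    if k_per_day == 0:
        return schedule, list(requests)
    compat = compat or default_compatibility()
    added_coils = choose_added_coils(k_per_day, saved_minutes_per_day, calib, candidates)

    req_list = list(requests)
    day_orders: dict[tuple[str, dt.date], list[str]] = {
        key: [s.request_id for s in slots] for key, slots in schedule.by_scanner_day().items()
    }
    days = sorted({d for (_, d) in day_orders})
    req_lookup = {r.request_id: r for r in req_list}
    serial = 0
    for day in days:
        for coil in added_coils:
            serial += 1
            # prefer a scanner-day already ending or containing a block of this coil
            candidates_sd = [
                (scanner, day)
                for scanner in compat.scanners_for(coil)
                if (scanner, day) in day_orders
            ]
            if not candidates_sd:
                raise CompatibilityError(f"no compatible scanner runs on {day} for {coil!r}")
            with_block = [
                sd
                for sd in candidates_sd
                if any(req_lookup[rid].coil == coil for rid in day_orders[sd])
            ]
            pool = with_block or candidates_sd
            target = min(pool, key=lambda sd: (len(day_orders[sd]), sd[0]))
            order = day_orders[target]
            insert_at = len(order)
            for i in range(len(order) - 1, -1, -1):
                if req_lookup[order[i]].coil == coil:
                    insert_at = i + 1
                    break
            if insert_at < len(order):
                anchor = req_lookup[order[insert_at - 1]]
                appt = anchor.appointment_datetime + dt.timedelta(minutes=1)
            else:
                appt = dt.datetime.combine(day, dt.time(22, 0))
            new_req = ExamRequest(
                request_id=f"X{day.strftime('%d')}{serial:04d}",
                patient_type="outpatient",
                gender="female",
                needs_contrast=False,
                priority=False,
                coil=coil,
                booking_datetime=appt
                - dt.timedelta(days=calib.coil_profiles[coil].mean_wait_days),
                appointment_datetime=min(
                    appt, dt.datetime.combine(day, dt.time(22, 59))
                ),
            )
            req_list.append(new_req)
            req_lookup[new_req.request_id] = new_req
            order.insert(insert_at, new_req.request_id)
    augmented = _build_slots(day_orders, schedule.policy_name + "+k", req_lookup)
    return augmented, req_list


def write_schedule(schedule: Schedule, path) -> None:
    """Write a schedule as CSV (scanner, day, session, slot index, request, coil)."""
    df = pd.DataFrame(
        [
            {
                "scanner_id": s.scanner_id,
                "day": s.day.isoformat(),
                "session": s.session,
                "slot_index": s.slot_index,
                "request_id": s.request_id,
                "coil": s.coil,
            }
            for s in schedule.slots
        ],
        columns=["scanner_id", "day", "session", "slot_index", "request_id", "coil"],
    )
    df.to_csv(path, index=False, lineterminator="\n")
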