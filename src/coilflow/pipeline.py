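"""End-to-end orchestration of the two experimental phases.

Phase 1 pairs a baseline (as-booked) run against the coil-grouped proposed
policy on identical request sets and seeds, and compares the daily
indicators with the rank-sum test.  Phase 2 converts the preparation
minutes saved by phase 1 into one, two and three extra examinations per
day, then reports utilization, overtime, NHI points, USD income and
per-coil wait-time reductions.

All randomness derives from ``seed0``; replication ``r`` uses ``seed0 + r``
for demand generation, routing and service-time draws, so identical
configurations produce identical artifacts.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import kpi_income, scheduling, sim_engine, stats_compare, synthetic_logs
from .kpi_income import KPIReport
from .scheduling import CompatibilityMatrix, Schedule
from .sim_engine import ServiceTimeConfig
from .synthetic_logs import CalibrationTables

__all__ = [
    "ScenarioConfig",
    "Phase1Result",
    "Phase2Result",
    "run_phase1",
    "run_phase2",
    "write_phase1_report",
    "write_phase2_report",
]

_WEEKDAY_NAMES = ("Sun.", "Mon.", "Tue.", "Wed.", "Thur.", "Fri.", "Sat.")


@dataclass
class ScenarioConfig:
    """One simulation scenario.

    ``daily_total`` defaults to the department's fixed appointment book of
    79 exams per day; set it to ``None`` for Poisson demand around the
    hourly calendar rates.  ``added_per_day`` above zero is only meaningful
    under the proposed policy (the baseline has no saved minutes to spend).
    """

    calibration: CalibrationTables = field(default_factory=synthetic_logs.default_calibration)
    compat: CompatibilityMatrix = field(default_factory=scheduling.default_compatibility)
    service: ServiceTimeConfig | None = None
    policy: str = "proposed"
    added_per_day: int = 0
    start_date: dt.date = dt.date(2016, 12, 1)
    n_days: int = 31
    n_replications: int = stats_compare.DEFAULT_REPLICATIONS
    seed0: int = 1
    daily_total: int | None = 79
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.policy not in ("baseline", "proposed"):
            raise ValueError(f"unknown policy {self.policy!r}")
        if self.added_per_day and self.policy != "proposed":
            raise ValueError("added_per_day > 0 requires the proposed policy")
        if not 0 <= self.added_per_day <= 3:
            raise ValueError("added_per_day must be in 0..3")
        if self.service is None:
            self.service = sim_engine.default_service_config(self.calibration)

    def content_hash(self) -> str:
        blob = json.dumps(
            {
                "calibration": self.calibration.to_dict(),
                "routing": {c: dict(sorted(r.items())) for c, r in sorted(self.compat.routing.items())},
                "policy": self.policy,
                "added_per_day": self.added_per_day,
                "start_date": self.start_date.isoformat(),
                "n_days": self.n_days,
                "n_replications": self.n_replications,
                "seed0": self.seed0,
                "daily_total": self.daily_total,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class Phase1Result:
    baseline_kpis: KPIReport
    proposed_kpis: KPIReport
    comparison: list[stats_compare.ComparisonRow]
    change_table: pd.DataFrame  # scanner x weekday mean daily coil changes
    saved_minutes_per_day: float
    config_hash: str


@dataclass
class Phase2Result:
    table: pd.DataFrame  # one row per added-patients scenario (k = 0..3)
    wait_reductions: dict[int, dict[str, dt.timedelta]]
    overtime_pvalues: dict[int, float]
    saved_minutes_per_day: float
    config_hash: str


def _run_arm(requests, schedule: Schedule, config: ScenarioConfig, seed: int):
    trace = sim_engine.run_simulation(
        schedule, requests, config.service, config.compat, seed=seed
    )
    return trace, kpi_income.compute_kpis(trace)


def _one_replication(config: ScenarioConfig, seed: int):
    requests = synthetic_logs.generate_requests(
        config.calibration,
        config.n_days,
        seed,
        start_date=config.start_date,
        daily_total=config.daily_total,
    )
    base_sched = scheduling.baseline_schedule(requests, config.compat, seed)
    prop_sched = scheduling.proposed_schedule(requests, config.compat, seed)
    base_trace, base_kpis = _run_arm(requests, base_sched, config, seed)
    prop_trace, prop_kpis = _run_arm(requests, prop_sched, config, seed)
    return requests, base_sched, prop_sched, base_trace, prop_trace, base_kpis, prop_kpis


def _pool_daily(reports: list[KPIReport]) -> dict[str, list[float]]:
    pooled: dict[str, list[float]] = {}
    for rep in reports:
        for name, values in rep.daily_values.items():
            pooled.setdefault(name, []).extend(values)
    return pooled


def _aggregate(reports: list[KPIReport]) -> KPIReport:
    """Average replication KPI reports into one (daily series pooled)."""
    pooled = _pool_daily(reports)

    def pool_mean_sd(name):
        arr = np.asarray(pooled[name])
        return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0

    scanners = sorted({s for r in reports for s in r.utilization_pct})
    coils = sorted({c for r in reports for c in r.wait_days})
    type_counts: dict[str, float] = {}
    for r in reports:
        for t, n in r.patient_type_counts.items():
            type_counts[t] = type_counts.get(t, 0) + n
    n_rep = len(reports)
    return KPIReport(
        daily_exam_time_mean_sd=pool_mean_sd("DailyMRIexamTime"),
        prep_time_mean_sd=pool_mean_sd("MRIexamPrepTime"),
        daily_overtime_mean_sd=pool_mean_sd("DailyOverTime"),
        daily_coil_changes_mean_sd=pool_mean_sd("DailyCoilChangeOccurrence"),
        utilization_pct={
            s: sum(r.utilization_pct.get(s, 0.0) for r in reports) / n_rep for s in scanners
        },
        wait_days={
            c: sum(r.wait_days[c] for r in reports if c in r.wait_days)
            / max(1, sum(c in r.wait_days for r in reports))
            for c in coils
        },
        total_exams=round(sum(r.total_exams for r in reports) / n_rep),
        patient_type_counts={t: round(n / n_rep) for t, n in type_counts.items()},
        daily_values=pooled,
    )


def _change_table(traces: list[pd.DataFrame], label: str) -> pd.DataFrame:
    """Mean daily coil changes per scanner and weekday across replications."""
    frames = []
    for trace in traces:
        per_day = trace.groupby(["scanner_id", "day"])["coil_changed"].sum().reset_index()
        per_day["weekday"] = per_day["day"].map(lambda d: _WEEKDAY_NAMES[(d.weekday() + 1) % 7])
        frames.append(per_day)
    allreps = pd.concat(frames)
    pivot = allreps.pivot_table(
        index="scanner_id", columns="weekday", values="coil_changed", aggfunc="mean"
    )
    pivot = pivot.reindex(columns=list(_WEEKDAY_NAMES))
    pivot.columns = [f"{c} ({label})" for c in pivot.columns]
    return pivot


def run_phase1(config: ScenarioConfig) -> Phase1Result:
    """Pair baseline and proposed policies on shared demand and compare.

    Requires ``policy='proposed'``: the phase needs both arms, and a
    baseline-only configuration is refused.
    """
    if config.policy != "proposed":
        raise ValueError("phase 1 compares both arms; configure policy='proposed'")
    base_reports, prop_reports = [], []
    base_traces, prop_traces = [], []
    for r in range(config.n_replications):
        seed = config.seed0 + r
        _, _, _, bt, pt, bk, pk = _one_replication(config, seed)
        base_reports.append(bk)
        prop_reports.append(pk)
        base_traces.append(bt)
        prop_traces.append(pt)
    base_kpis = _aggregate(base_reports)
    prop_kpis = _aggregate(prop_reports)
    comparison = stats_compare.compare_scenarios(
        _pool_daily(base_reports), _pool_daily(prop_reports)
    )
    table = pd.concat(
        [_change_table(base_traces, "baseline"), _change_table(prop_traces, "proposed")],
        axis=1,
    )
    exams_per_day = base_kpis.total_exams / config.n_days
    saved = kpi_income.saved_minutes_per_day(
        base_kpis.prep_time_mean_sd[0], prop_kpis.prep_time_mean_sd[0], exams_per_day
    )
    return Phase1Result(
        baseline_kpis=base_kpis,
        proposed_kpis=prop_kpis,
        comparison=comparison,
        change_table=table,
        saved_minutes_per_day=saved,
        config_hash=config.content_hash(),
    )


def run_phase2(config: ScenarioConfig, phase1: Phase1Result | None = None) -> Phase2Result:
    """Capacity experiment: spend the saved minutes on k = 1..3 extra exams/day."""
    if config.policy != "proposed":
        raise ValueError("phase 2 builds on the proposed policy")
    if phase1 is None:
        phase1 = run_phase1(config)
    saved = phase1.saved_minutes_per_day
    seed = config.seed0
    requests, _, prop_sched, base_trace, prop_trace, base_kpis, _ = _one_replication(
        config, seed
    )
    baseline_total = phase1.baseline_kpis.total_exams
    base_overtime = phase1.baseline_kpis.daily_values["DailyOverTime"]

    rows = []
    wait_reductions: dict[int, dict[str, dt.timedelta]] = {}
    overtime_p: dict[int, float] = {}
    for k in range(0, 4):
        if k == 0:
            sched_k, reqs_k = prop_sched, requests
        else:
            sched_k, reqs_k = scheduling.augment_schedule(
                prop_sched, requests, k, saved, config.calibration, config.compat
            )
        trace_k, kpis_k = _run_arm(reqs_k, sched_k, config, seed)
        income = kpi_income.points_and_income(k, config.n_days)
        income.pct_increase = kpi_income.percent_increase(
            k * config.n_days, baseline_total
        )
        _, p_ot = stats_compare.rank_sum_test(
            base_overtime, kpis_k.daily_values["DailyOverTime"]
        )
        overtime_p[k] = p_ot
        if k > 0:
            wait_reductions[k] = {
                coil: kpi_income.wait_time_reduction(base_trace, trace_k, coil)
                for coil in scheduling.DEFAULT_AUGMENT_COILS
                if coil in set(base_trace["coil"]) and coil in set(trace_k["coil"])
            }
        row = {
            "added_per_day": k,
            "total_patients": baseline_total + k * config.n_days,
            "pct_increase": income.pct_increase if k else 0.0,
            "overtime_minutes": kpis_k.daily_overtime_mean_sd[0],
            "points_without_contrast": income.points_without_contrast,
            "points_with_contrast": income.points_with_contrast,
            "usd_without": income.usd_without,
            "usd_with": income.usd_with,
            "overtime_p_vs_baseline": p_ot,
        }
        for s, u in sorted(kpis_k.utilization_pct.items()):
            row[f"util_{s}"] = u
        rows.append(row)
    return Phase2Result(
        table=pd.DataFrame(rows),
        wait_reductions=wait_reductions,
        overtime_pvalues=overtime_p,
        saved_minutes_per_day=saved,
        config_hash=config.content_hash(),
    )


def _comparison_frame(rows: list[stats_compare.ComparisonRow]) -> pd.DataFrame:
    out = []
    for row in rows:
        a, b = np.asarray(row.group_a), np.asarray(row.group_b)
        out.append(
            {
                "indicator": row.indicator_name,
                "mean_a": a.mean(),
                "sd_a": a.std(ddof=1) if a.size > 1 else 0.0,
                "mean_b": b.mean(),
                "sd_b": b.std(ddof=1) if b.size > 1 else 0.0,
                "statistic": row.statistic,
                "p_value": row.p_value,
                "significant": row.significant,
            }
        )
    return pd.DataFrame(out)


def write_phase1_report(result: Phase1Result, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": result.config_hash, "saved_minutes_per_day": result.saved_minutes_per_day}
    (out / "phase1_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    result.baseline_kpis.to_frame().to_csv(out / "phase1_baseline_kpis.csv", index=False)
    result.proposed_kpis.to_frame().to_csv(out / "phase1_proposed_kpis.csv", index=False)
    _comparison_frame(result.comparison).to_csv(out / "phase1_comparison.csv", index=False)
    result.change_table.to_csv(out / "phase1_coil_changes_by_weekday.csv")


def write_phase2_report(result: Phase2Result, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "config_hash": result.config_hash,
        "saved_minutes_per_day": result.saved_minutes_per_day,
        "overtime_pvalues": {str(k): v for k, v in result.overtime_pvalues.items()},
        "wait_reductions": {
            str(k): {c: kpi_income.format_duration(d) for c, d in v.items()}
            for k, v in result.wait_reductions.items()
        },
    }
    (out / "phase2_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    result.table.to_csv(out / "phase2_capacity_income.csv", index=False)
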