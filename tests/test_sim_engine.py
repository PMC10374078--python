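"""Event engine: prep-time calibration, scanner selection, conservation,
non-overlap and agreement with the static change counter."""

import datetime as dt

import pandas as pd
import pytest

import coilflow as cf
from coilflow.sim_engine import ScannerState, SimulationError, read_trace, write_trace

from conftest import make_request


class TestCalibratePrepComponents:
    def test_published_operating_points(self):
        """The two published (mean prep, changes/day) points at 79 exams/day
        identify a ~3.55-min changeover on a ~3.45-min base setup."""
        base, change = cf.calibrate_prep_components(
            5.27, 40.38 / 79, 4.04, 13.04 / 79
        )
        assert change == pytest.approx(97.17 / 27.34 * 79 / 79, abs=1e-9)
        assert change == pytest.approx(3.555, abs=2e-3)
        assert base == pytest.approx(3.45, abs=5e-3)

    def test_zero_rate_pins_intercept(self):
        base, change = cf.calibrate_prep_components(5.0, 1.0, 3.0, 0.0)
        assert (base, change) == (3.0, 2.0)

    def test_equal_rates_singular(self):
        with pytest.raises(ValueError, match="singular"):
            cf.calibrate_prep_components(5.27, 0.5, 5.27, 0.5)

    def test_avoided_changes_recover_saved_minutes(self):
        """Changeover minutes x avoided daily changes reproduces the daily
        prep-minute saving implied by the operating points, within 0.5 min."""
        _, change = cf.calibrate_prep_components(5.27, 40.38 / 79, 4.04, 13.04 / 79)
        assert (40.38 - 13.04) * change == pytest.approx(97.17, abs=0.5)


class TestPrepTime:
    def test_matching_coil_base_only(self, service):
        state = ScannerState("B", frozenset({"Torso"}), mounted_coil="Torso")
        assert cf.prep_time(state, make_request(), service) == pytest.approx(
            service.base_setup_minutes
        )

    def test_bare_scanner_counts_as_change(self, service):
        state = ScannerState("B", frozenset({"Torso"}), mounted_coil=None)
        assert cf.prep_time(state, make_request(), service) == pytest.approx(
            service.base_setup_minutes + service.coil_change_minutes
        )

    def test_calibrated_change_is_about_7_minutes(self, service):
        state = ScannerState("B", frozenset({"Torso", "Spine"}), mounted_coil="Spine")
        assert cf.prep_time(state, make_request(), service) == pytest.approx(7.0, abs=0.1)


class TestSelectScanner:
    def _states(self, busy=None):
        compat = cf.default_compatibility()
        states = {s: ScannerState(s, compat.usable[s]) for s in "ABCD"}
        for s, until in (busy or {}).items():
            states[s].busy_until = until
        return states

    def test_cardiac_goes_to_c(self):
        assert cf.select_scanner(make_request(coil="Card."), self._states()) == "C"

    def test_scheduled_scanner_busy_falls_to_idle_compatible(self):
        now = dt.datetime(2016, 12, 1, 9, 0)
        states = self._states(busy={"B": now + dt.timedelta(minutes=60)})
        got = cf.select_scanner(
            make_request(coil="Torso"), states, scheduled_scanner="B", now=now
        )
        assert got == "A"  # earliest-free compatible

    def test_unmountable_coil_rejected(self):
        states = {"A": ScannerState("A", frozenset({"Spine"}))}
        with pytest.raises(SimulationError, match="Card"):
            cf.select_scanner(make_request(coil="Card."), states)


class TestRunSimulation:
    def test_empty_schedule_empty_trace(self, service, compat):
        trace = cf.run_simulation(cf.Schedule(slots=[], policy_name="baseline"), [], service, compat)
        assert trace.empty

    def test_same_coil_day_no_changes_after_mount(self, service, compat):
        appt0 = dt.datetime(2016, 12, 1, 9, 0)
        reqs = [
            make_request(rid=f"R{i}", coil="Torso", appt=appt0 + dt.timedelta(minutes=30 * i))
            for i in range(3)
        ]
        matrix = cf.CompatibilityMatrix(usable=compat.usable, routing={"Torso": {"B": 1.0}})
        sched = cf.baseline_schedule(reqs, matrix, seed=0)
        svc = cf.default_service_config(cf.default_calibration())
        svc.carry_coil_overnight = True
        trace = cf.run_simulation(sched, reqs, svc, compat, seed=0)
        # bare scanner: first exam mounts the coil, the rest are free
        assert trace["coil_changed"].tolist() == [True, False, False]

    def test_conservation_and_slot_order(self, week_requests, compat, service):
        sched = cf.baseline_schedule(week_requests, compat, seed=11)
        trace = cf.run_simulation(sched, week_requests, service, compat, seed=11)
        assert len(trace) == len(sched.slots) == len(week_requests)
        order = {s.request_id: (s.scanner_id, s.day, s.slot_index) for s in sched.slots}
        for (scanner, day), group in trace.groupby(["scanner_id", "day"]):
            idx = [order[r][2] for r in group["request_id"]]
            assert idx == sorted(idx)

    def test_no_overlap_per_scanner(self, week_traces):
        for trace in week_traces:
            for _, group in trace.groupby("scanner_id"):
                g = group.sort_values("prep_start")
                assert (g["table_off"].values[:-1] <= g["prep_start"].values[1:]).all()
                assert (g["table_off"] > g["table_on"]).all()
                assert (g["table_on"] >= g["prep_start"]).all()

    def test_changed_flags_match_static_counter(self, week_requests, compat, service):
        """Summed coil_changed flags per scanner-day equal count_coil_changes
        on the executed coil sequence — the engine and the audit agree."""
        for policy in (cf.baseline_schedule, cf.proposed_schedule):
            sched = policy(week_requests, compat, 11)
            trace = cf.run_simulation(sched, week_requests, service, compat, seed=11)
            mounted = {}
            for (day, scanner), group in trace.sort_values(
                ["day", "scanner_id", "table_on"]
            ).groupby(["day", "scanner_id"], sort=True):
                coils = group["coil"].tolist()
                expected = cf.count_coil_changes(coils, mounted.get(scanner))
                assert group["coil_changed"].sum() == expected
                mounted[scanner] = coils[-1]

    def test_deterministic_under_seed(self, week_requests, compat, service):
        sched = cf.baseline_schedule(week_requests, compat, seed=11)
        t1 = cf.run_simulation(sched, week_requests, service, compat, seed=4)
        t2 = cf.run_simulation(sched, week_requests, service, compat, seed=4)
        t3 = cf.run_simulation(sched, week_requests, service, compat, seed=5)
        pd.testing.assert_frame_equal(t1, t2)
        assert not t1["table_off"].equals(t3["table_off"])

    def test_unknown_request_id_named(self, compat, service):
        slot = cf.ScheduleSlot("B", dt.date(2016, 12, 1), "morning", 0, "GHOST", "Torso")
        with pytest.raises(SimulationError, match="GHOST"):
            cf.run_simulation(cf.Schedule([slot], "baseline"), [], service, compat)

    def test_contrast_runs_longer_on_average(self, calib, compat, service):
        appt0 = dt.datetime(2016, 12, 1, 7, 30)
        mk = lambda i, c: make_request(
            rid=f"R{i}", coil="Torso", appt=appt0 + dt.timedelta(minutes=i), contrast=c
        )
        reqs = [mk(i, i % 2 == 0) for i in range(200)]
        matrix = cf.CompatibilityMatrix(usable=compat.usable, routing={"Torso": {"B": 1.0}})
        sched = cf.baseline_schedule(reqs, matrix, seed=0)
        trace = cf.run_simulation(sched, reqs, service, compat, seed=0)
        dur = (trace["table_off"] - trace["table_on"]).dt.total_seconds() / 60
        mean_c = dur[trace["needs_contrast"]].mean()
        mean_n = dur[~trace["needs_contrast"]].mean()
        assert mean_c > mean_n

    def test_trace_csv_round_trip(self, week_traces, tmp_path):
        trace = week_traces[0]
        path = tmp_path / "trace.csv"
        write_trace(trace, path)
        back = read_trace(path)
        assert len(back) == len(trace)
        pd.testing.assert_series_equal(back["table_off"], trace["table_off"])
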