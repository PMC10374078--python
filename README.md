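# coilflow

Hybrid discrete-event / agent-based simulation of an MRI department, built
to answer a scheduling question radiology managers actually face: **how
much service time is lost to MRI coil changes, and what is it worth to
group same-coil examinations together?**

Each of the department's four scanners (A–D) can mount only a subset of 11
receiver coil types; every time consecutive exams need different coils the
technologist swaps hardware, adding ~3.5 minutes of preparation. `coilflow`
generates a synthetic month of exam demand with the department's published
structure, runs an as-booked **baseline** schedule and a coil-grouped
**proposed** schedule through an event engine with scanner contention, and
quantifies the difference in two phases:

1. **Phase 1** — coil changes per day, preparation time per exam, and
   overtime under both policies, compared with the Wilcoxon rank-sum test
   over daily values (8 replications).
2. **Phase 2** — the saved preparation minutes are spent on one, two or
   three extra examinations per day, reported as scanner utilization,
   overtime, NHI global-budget points (6,500 per exam without contrast,
   11,500 with) and USD income (points × 0.847 NTD/point ÷ 30 NTD/USD),
   plus per-coil wait-time changes.

The core quantities, in the field's usual notation: preparation time per
exam is modelled as `prep = base + change·𝟙[coil differs]`, identified from
two operating points `(p̄₁, r₁), (p̄₂, r₂)` of mean prep vs changes-per-exam
by solving the 2×2 system `p̄ᵢ = base + rᵢ·change`; daily saved minutes are
`(p̄_before − p̄_after) × exams/day`; a grouped scanner-day with `d` distinct
coils needs exactly `d−1` changes when the mounted coil is among them — the
permutation-minimum — versus the as-booked count.

## Worked example

```python
import coilflow as cf

cfg = cf.ScenarioConfig(seed0=1, n_replications=8)   # 31-day December, 79 exams/day
p1 = cf.run_phase1(cfg)
b, p = p1.baseline_kpis, p1.proposed_kpis
print(f"coil changes/day: {b.daily_coil_changes_mean_sd[0]:.2f} -> {p.daily_coil_changes_mean_sd[0]:.2f}")
print(f"prep min/exam:    {b.prep_time_mean_sd[0]:.2f} -> {p.prep_time_mean_sd[0]:.2f}")
print(f"saved min/day:    {p1.saved_minutes_per_day:.2f}")

p2 = cf.run_phase2(cfg, phase1=p1)
print(p2.table[["added_per_day", "total_patients", "pct_increase",
                "points_with_contrast", "usd_with"]].to_string(index=False))
```

prints

```
coil changes/day: 54.09 -> 19.84
prep min/exam:    5.89 -> 4.35
saved min/day:    121.74
 added_per_day  total_patients  pct_increase  points_with_contrast  usd_with
             0            2449          0.00                     0         0
             1            2480          1.27                356500     10065
             2            2511          2.53                713000     20130
             3            2542          3.80               1069500     30196
```

Reading: grouping cuts coil changes from ~54 to ~20 per day across the four
scanners, dropping mean preparation from 5.89 to 4.35 min/exam and freeing
~122 min/day (the comparison is significant at α = 0.05; the rank-sum
p-value for coil changes is ~1e-83 over 8 × 31 daily values). Spending that
time on three extra exams/day grows the month from 2,449 to 2,542 patients
(+3.80%) and is worth 604,500–1,069,500 points ≈ US$17,067–30,196 per month
depending on contrast use. Absolute KPI levels depend on the synthetic
demand and the configurable routing matrix; directions and the income
arithmetic do not.

The same experiments are available from the shell:

```bash
coilflow generate --seed 1 --days 31 --out log.csv
coilflow phase1 --seed 1 --reps 8 --out report/
coilflow phase2 --seed 1 --reps 8 --out report/
coilflow compare report/a.csv report/b.csv --column DailyOverTime
```

## Layout

```
src/coilflow/
  synthetic_logs.py   # calibration tables + synthetic exam-request CSV logs
  scheduling.py       # baseline & coil-grouped policies, change counting, augmentation
  sim_engine.py       # schedule-driven event engine with scanner agents
  kpi_income.py       # validation indicators, KPIs, points/USD projections
  stats_compare.py    # exact/asymptotic rank-sum, replication summaries
  pipeline.py         # phase-1/phase-2 orchestration and report artifacts
  cli.py              # `coilflow` command-line verbs
docs/methods.md       # model assumptions, calibration choices, limitations
```
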