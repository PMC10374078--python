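# Methods

## The system being modelled

An MRI department with four scanners (A–D) runs a 16-hour service day
(07:00–23:00). Each examination needs one of 11 receiver coil types
(standard head, cardiac, 8-inch head, neurovascular, breast, torso, spine,
lower extremity, flexible torso-and-head, knee, shoulder); each scanner can
mount only a subset (A = 8, B = 9, C = 10, D = 7 coil types; the cardiac
coil mounts only on scanner C, the standard head coil routes 3%/97% to
C/D). When consecutive exams on a scanner need different coils, the
technologist must swap the coil, which consumes preparation time. The
package quantifies how much service time is reclaimed by re-ordering the
appointment book so same-coil exams run back-to-back, and what that time is
worth in extra examinations and reimbursement income.

Patients flow through five stations: registration → dressing → (IV contrast
setup) → waiting → examination → (IV removal). The examination itself is
one scan segment, or two when a contrast agent is injected.

## Synthetic demand generator

There is no public examination log, so `synthetic_logs` generates one with
the published statistical structure of a 31-day December:

* **Volume** — an hourly demand calendar booking 2,449/31 ≈ 79 exams/day,
  uniform over the 16 service hours (the source reports no intraday
  profile). Counts per hour are Poisson, or exact (multinomial over hours)
  when a fixed daily book is requested; the experiments use the fixed book
  of 79, matching a department that fills its appointment grid.
* **Patient mix** — outpatient/emergency/inpatient at 74.34/5.93/19.74%
  (normalised; the printed shares carry a 1e-4 rounding excess). Emergency
  patients carry a priority flag.
* **Coils** — per-coil demand shares use the four published monthly exam
  counts (flexible torso-and-head 53, shoulder 41, 8-inch head 398, torso
  1,261 of 2,447) and spread the remaining ~28% uniformly over the other
  seven coils. Shares are configuration-overridable; no published table
  fixes them all.
* **Waits** — the appointment is drawn from the calendar; the booking time
  is the appointment minus an exponential wait with the coil's published
  mean (0.96–22 days). Only means are published, so the exponential is the
  maximum-entropy choice on the positive half-line.
* **Contrast** — probability 0.4 per exam (not published; the income
  projections deliberately bracket the all-without/all-with cases and never
  depend on it).

What the generator does **not** emulate: seasonal or weekday demand
variation, intraday arrival peaks, no-shows and cancellations, a waiting
list that re-books freed slots, and correlation between coil type and
patient type. Tests passing on this demand therefore certify the machinery
(conservation, ordering, counting, arithmetic) and the direction of policy
effects, not the hospital's exact KPI magnitudes.

## Scheduling policies

**Baseline** routes each request to a scanner by sampling the coil's
routing probabilities and runs each scanner-day in appointment order. Only
two routing rows are published (cardiac → C at 100%; standard head → C/D at
3%/97%); the remaining rows default to an equal split over the scanners
that can mount the coil and are fully configuration-exposed. The usable-set
sizes (8/9/10/7) are honoured by the default matrix.

**Proposed** keeps the same scanner assignment (same seed, so the two arms
are paired) and re-orders each scanner-day into contiguous same-coil
blocks. Block order is chosen to minimise swaps while perturbing the
existing book as little as possible:

1. the block of the coil already mounted at day start runs first (no
   morning changeover), unless that coil is also the day's original closer;
2. middle blocks run by descending size, ties by first appearance;
3. the block of the day's *original* closing coil runs last.

Rule 3 is the load-bearing design choice: by ending every day in the same
mounted-coil state as the as-booked schedule, re-grouping one day can never
degrade a later day, and each scanner-day's change count is provably at
most the as-booked count (the count is d−1 when the mounted coil is among
the day's d distinct coils and is not the closer, d otherwise, while any
sequence over d distinct coils needs at least that many swaps). A simpler
"largest block first" rule was considered and rejected: it can shift a
day's closing coil and make the next day worse than baseline.

Emergency patients are moved to the front of their own coil's block rather
than to the front of the day: they are served first among equals without
breaking block contiguity (an absolute-front rule would re-introduce
changeovers and void the dominance guarantee).

The week is banded Sunday–Monday / Tuesday–Wednesday / Thursday–Saturday;
`weekday_group` exposes the banding, and the overnight carry of the mounted
coil chains blocks across consecutive days within a band.

**Capacity augmentation** (phase 2) appends k ∈ {1,2,3} exams/day whose
coils come from the four published target types (flexible torso-and-head
40 min, shoulder 34, 8-inch head 28, torso 36, by median duration). The
multiset of k coils is chosen by exhaustive search over combinations with
replacement to maximise total median duration subject to fitting in the
saved minutes/day; with 97.17 saved minutes and k = 3 this selects
{TorsoHead, 8chHead, 8chHead} (96 min — no three *distinct* coils from the
set fit under the budget). Infeasibility (e.g. k = 1 with 10 saved minutes
when every median is ≥ 25) raises an explicit error rather than silently
truncating. Added exams are inserted adjacent to an existing block of the
same coil so they cost no extra changeover.

## Event engine

The engine is a schedule-driven sequential event loop: because the policy
fixes each scanner-day's service order, scanner contention reduces to
`start = max(patient ready, scanner free)` per slot, and no general-purpose
event-calendar kernel is needed. Per exam:

* the patient takes the scanner-day's i-th booked appointment time (a
  re-ordering policy swaps patients between the day's appointment slots
  rather than inventing new arrival times), then passes registration
  (3 min), dressing (5 min) and, for contrast, IV setup (5 min) — each
  triangular ±50% around the mode, as these times are unrecorded in the
  source log and set by operational rule of thumb;
* scanner preparation is `base_setup + coil_change·[coil differs]`. The two
  components are identified by `calibrate_prep_components` from the two
  published operating points (mean prep 5.27 min at 40.38 changes/day;
  4.04 min at 13.04 changes/day; 79 exams/day): changeover ≈ 3.55 min,
  base ≈ 3.45 min. Consistency: 27.34 avoided changes × 3.554 min ≈
  97.2 min/day, matching the published saving within rounding;
* scan duration is lognormal with the coil's median as the anchor
  (σ = 0.25), times a contrast factor of 1.1 for two-segment contrast
  exams, times a global scale solved in closed form so the expected
  population mean equals the calibration target (33.03 min). The anchor
  medians alone would imply a ≈ 36 min demand-weighted mean, above the
  published population mean, hence the explicit scale;
* the mounted coil persists overnight by default (`carry_coil_overnight`);
  a reset-to-bare flag is available.

Degenerate inputs: an empty schedule yields an empty trace; a slot whose
request is unknown or whose coil the scanner cannot mount raises named
errors; exams booked near the 23:00 close are still served (producing
overtime) rather than dropped, which is what makes the conservation
invariant (|trace| = |slots|) unconditional.

## Indicators, income and statistics

`compute_kpis` reduces a trace to the department's indicator set: on-table
minutes per exam and prep minutes per exam averaged per day; daily coil
changes; overtime = max(0, last off-table − 23:00) per scanner-day,
averaged across scanners within a day (the clamp keeps the indicator a
cost; early closes do not offset late ones); utilization = occupied
(prep + scan) minutes over 960 per scanner, capped at 100%; per-coil mean
booking-to-table waits. Mean imputation of missing on/off-table durations
is provided for ingesting incomplete logs.

Income: each added exam earns 6,500 NHI global-budget points without
contrast or 11,500 with; USD = points × 0.847 NTD/point ÷ 30 NTD/USD,
rounded to whole dollars (both factors are explicit parameters; this pair
reproduces the published USD figures exactly). Percentages are reported to
two decimals, matching the published presentation.

Scenario comparison uses the two-sided Wilcoxon rank-sum test at α = 0.05
on daily indicator series (n = 31 days by default). For both samples ≤ 10
the p-value is exact enumeration over all C(n, n_a) midrank assignments
(two-sided as twice the smaller tail, capped at 1), which handles ties —
including identical samples, where p = 1 — without a continuity fudge;
larger samples use the normal approximation with tie and continuity
corrections. Replication follows the eight-run protocol with Student-t 95%
confidence half-widths; replication r consumes only seed0 + r.

## Problem sizes and limitations

The shipped experiments use a 31-day month at 79 exams/day (2,449 exams)
with 8 replications for the headline run and a 7-day, 2-replication
configuration in the test suite; both complete in seconds on one core.

Known limitations: the default routing fill-in concentrates long cardiac
exams on scanner C, so simulated utilization and overtime are less balanced
than the published department's (magnitudes are routing- and
demand-dependent; the package asserts directions and structural invariants
instead). Because the generator books appointments directly instead of
modelling a re-booking waiting list, phase-2 wait-time reductions appear as
hours rather than the multi-day reductions a backlog model would show.
Scanner maintenance windows and patient mobility differences are out of
scope.
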