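"""Replication summaries and rank-sum comparison of simulation output.

Simulation indicators (daily overtime, coil changes, preparation time, ...)
are non-normally distributed, so scenarios are compared with the two-sided
Wilcoxon rank-sum (Mann-Whitney) test at alpha = 0.05.  For small samples
(both n <= 10) the p-value comes from exact enumeration of all rank
assignments, using midranks so tied data — including identical samples —
are handled; larger samples use the normal approximation with tie
correction and continuity correction.

Replication follows the department's output-analysis protocol: eight
replications per scenario with 95% confidence intervals on every indicator.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "ALPHA",
    "DEFAULT_REPLICATIONS",
    "ReplicationSummary",
    "ComparisonRow",
    "rank_sum_test",
    "replicate",
    "compare_scenarios",
]

ALPHA = 0.05
DEFAULT_REPLICATIONS = 8
_EXACT_MAX_N = 10


@dataclass
class ReplicationSummary:
    """Per-indicator summary over replicated simulation runs."""

    indicator_name: str
    values: list[float]
    mean: float
    sd: float | None  # None when a single replication leaves sd undefined
    ci_half_width: float | None
    n_replications: int


@dataclass
class ComparisonRow:
    indicator_name: str
    group_a: list[float] = field(repr=False)
    group_b: list[float] = field(repr=False)
    statistic: float = 0.0
    p_value: float = 1.0
    significant: bool = False


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def _exact_p(ranks: np.ndarray, n_a: int, w_obs: float) -> float:
    """Two-sided exact p: enumerate all C(n, n_a) assignments of the pooled
    midranks to group a and double the smaller tail of the rank-sum W."""
    n = len(ranks)
    le = ge = total = 0
    eps = 1e-9
    for combo in itertools.combinations(range(n), n_a):
        w = ranks[list(combo)].sum()
        total += 1
        if w <= w_obs + eps:
            le += 1
        if w >= w_obs - eps:
            ge += 1
    p = 2.0 * min(le, ge) / total
    return min(p, 1.0)


def _approx_p(ranks: np.ndarray, n_a: int, w_obs: float) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n = len(ranks)
    n_b = n - n_a
    mean_w = n_a * (n + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    var_w = n_a * n_b / 12.0 * (n + 1 - tie_term)
    if var_w <= 0:
        return 1.0
    diff = w_obs - mean_w
    z = (diff - math.copysign(0.5, diff)) / math.sqrt(var_w) if diff != 0 else 0.0
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def rank_sum_test(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum / Mann-Whitney test.

    Returns ``(U_a, p)`` where ``U_a`` is the Mann-Whitney statistic of
    ``sample_a``.  Exact enumeration over midrank assignments when both
    samples have at most 10 observations; normal approximation with tie and
    continuity corrections otherwise.  Empty samples are rejected.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    w_obs = float(ranks[: a.size].sum())
    u_a = w_obs - a.size * (a.size + 1) / 2.0
    if a.size <= _EXACT_MAX_N and b.size <= _EXACT_MAX_N:
        p = _exact_p(ranks, a.size, w_obs)
    else:
        p = _approx_p(ranks, a.size, w_obs)
    return u_a, p


def replicate(run_fn, n_replications: int, seed0: int) -> dict[str, ReplicationSummary]:
    """Run a scenario ``n_replications`` times with seeds ``seed0 .. seed0+n-1``.

    ``run_fn(seed)`` must return a mapping of indicator name to a scalar for
    that replication.  Replication ``r`` depends only on seed ``seed0 + r``,
    so summaries are deterministic given ``(run_fn, n, seed0)``.
    """
    if n_replications < 1:
        raise ValueError("n_replications must be >= 1")
    per_indicator: dict[str, list[float]] = {}
    for r in range(n_replications):
        seed = seed0 + r
        try:
            result = run_fn(seed)
        except Exception as exc:
            raise RuntimeError(f"replication with seed {seed} failed: {exc}") from exc
        for name, value in result.items():
            per_indicator.setdefault(name, []).append(float(value))
    summaries = {}
    for name, values in per_indicator.items():
        arr = np.asarray(values)
        n = arr.size
        if n > 1:
            sd = float(arr.std(ddof=1))
            half = float(sps.t.ppf(1 - ALPHA / 2, n - 1) * sd / math.sqrt(n))
        else:
            sd = half = None
        summaries[name] = ReplicationSummary(
            indicator_name=name,
            values=[float(v) for v in values],
            mean=float(arr.mean()),
            sd=sd,
            ci_half_width=half,
            n_replications=n,
        )
    return summaries


def compare_scenarios(
    values_a: dict[str, list[float]], values_b: dict[str, list[float]]
) -> list[ComparisonRow]:
    """Rank-sum comparison of two scenarios, one row per shared indicator.

    ``values_*`` map indicator names to per-day (or per-replication) series.
    Mismatched indicator sets are an error naming the difference.
    """
    only_a = sorted(set(values_a) - set(values_b))
    only_b = sorted(set(values_b) - set(values_a))
    if only_a or only_b:
        raise ValueError(
            f"indicator sets differ: only in a: {only_a}; only in b: {only_b}"
        )
    rows = []
    for name in sorted(values_a):
        stat, p = rank_sum_test(values_a[name], values_b[name])
        rows.append(
            ComparisonRow(
                indicator_name=name,
                group_a=[float(v) for v in values_a[name]],
                group_b=[float(v) for v in values_b[name]],
                statistic=stat,
                p_value=p,
                significant=p < ALPHA,
            )
        )
    return rows
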