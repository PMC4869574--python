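"""Life tables, median-survival statistics, and mortality-trajectory analysis.

The central object is the *mortality trajectory*: the natural log of the
daily probability of death plotted against age in days. Under Gompertz
mortality this trajectory is linear, so cohort comparisons reduce to two
numbers: a vertical *displacement* between parallel trajectories (damage
accumulated in early life) and a *gradient* difference between their slopes
(ongoing acceleration of ageing). ``accrual_rate`` converts a displacement
accrued over a known exposure window into an equivalent daily gradient
increase, making the two directly comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

EVENT_COLUMNS = ["fly_id", "genotype", "subgroup", "induction", "death_day", "censored"]

__all__ = [
    "EVENT_COLUMNS",
    "LinearFit",
    "MortalityTrajectory",
    "GradientDecomposition",
    "read_events",
    "write_events",
    "subgroup_medians",
    "median_survival",
    "compare_medians",
    "life_table",
    "mortality_trajectory",
    "fit_trajectory",
    "displacement",
    "accrual_rate",
    "gradient_delta",
    "combine_estimates",
    "relative_excess",
    "round_half_up",
]


@dataclass(frozen=True)
class LinearFit:
    """OLS fit of ln(daily death probability) on age in days."""

    slope: float          # day^-1, the trajectory "gradient"
    intercept: float      # ln-probability at day 0
    slope_se: float
    r_squared: float
    n_points: int

    def predict(self, days: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(days, dtype=float)


@dataclass(frozen=True)
class MortalityTrajectory:
    """Trimmed ln daily-death-probability series for one cohort."""

    days: np.ndarray
    ln_daily_prob: np.ndarray
    trim_fraction: float = 0.05

    def __post_init__(self) -> None:
        if len(self.days) != len(self.ln_daily_prob):
            raise ValueError("days and ln_daily_prob must have equal length")


@dataclass(frozen=True)
class GradientDecomposition:
    """Early-life displacement and late-life gradient terms for one stressor."""

    displacement: float    # ln-hazard units
    window_days: float
    accrual_rate: float    # day^-1, displacement / window
    gradient_delta: float  # day^-1, slope difference of mature trajectories


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    df["censored"] = df["censored"].astype(bool)
    return df


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def _subgroup_median(death_days: np.ndarray, censored: np.ndarray) -> float:
    """Smallest day by which at least half the subgroup has died (lower median)."""
    n = len(death_days)
    if n == 0 or censored.all():
        raise ValueError("subgroup has no uncensored deaths")
    days = np.sort(death_days[~censored])
    need = 0.5 * n
    cum = np.arange(1, len(days) + 1)
    idx = np.searchsorted(cum, need, side="left")
    if idx >= len(days):
        raise ValueError("fewer than half the subgroup died before censoring")
    return float(days[idx])


def subgroup_medians(events: pd.DataFrame, group_col: str = "genotype") -> pd.DataFrame:
    rows = []
    for (group, sub), g in events.groupby([group_col, "subgroup"], sort=True):
        med = _subgroup_median(g["death_day"].to_numpy(), g["censored"].to_numpy())
        rows.append({group_col: group, "subgroup": sub, "median": med})
    return pd.DataFrame(rows)


def median_survival(events: pd.DataFrame, group_col: str = "genotype") -> pd.DataFrame:
    """Per-group mean and sd of subgroup median survivals.

    Subgroup medians, not individual lifespans, are the unit of analysis: each
    subgroup median is treated as one estimate of the group's typical lifespan.
    """
    meds = subgroup_medians(events, group_col)
    out = (
        meds.groupby(group_col)["median"]
        .agg(mean_median="mean", sd_median="std", n_subgroups="count")
        .reset_index()
    )
    return out


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p-value by enumeration over label assignments.

    Uses midranks so ties are handled; the null distribution of the rank sum
    is built by dynamic programming over doubled midranks (integers), which is
    equivalent to enumerating all C(n, n_x) assignments.
    """
    pooled = np.concatenate([x, y])
    r2 = np.rint(2 * stats.rankdata(pooled)).astype(int)
    n, nx = len(pooled), len(x)
    w_obs = int(r2[:nx].sum())
    total = int(r2.sum())
    # dp[k, s] = number of k-subsets of the midranks with doubled-rank sum s
    dp = np.zeros((nx + 1, total + 1))
    dp[0, 0] = 1.0
    for r in r2:
        for k in range(min(nx, 1_000_000) - 1, -1, -1):
            dp[k + 1, r:] += dp[k, : total + 1 - r]
    dist = dp[nx]
    n_assign = math.comb(n, nx)
    mean_w = nx * total / n
    dev = abs(w_obs - mean_w)
    sums = np.arange(total + 1)
    p = dist[np.abs(sums - mean_w) >= dev - 1e-9].sum() / n_assign
    return float(min(p, 1.0))


def compare_medians(medians_a: Sequence[float], medians_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum test on two sets of subgroup medians.

    Exact enumeration for combined n <= 20; normal approximation with tie
    correction otherwise.
    """
    a = np.asarray(medians_a, dtype=float)
    b = np.asarray(medians_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 subgroup medians per group")
    if len(a) + len(b) <= 20:
        return _exact_ranksum_p(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def life_table(death_days: np.ndarray) -> pd.DataFrame:
    """Daily life table for a set of (already selected) death events.

    at_risk on day d counts individuals with death_day >= d among the given
    events; daily_death_prob = deaths / at_risk, the chance of dying over the
    coming 24 hours.
    """
    days_sorted = np.sort(np.asarray(death_days))
    days, counts = np.unique(days_sorted, return_counts=True)
    at_risk = len(days_sorted) - np.searchsorted(days_sorted, days, side="left")
    return pd.DataFrame(
        {
            "day": days,
            "at_risk": at_risk,
            "deaths": counts,
            "daily_death_prob": counts / at_risk,
        }
    )


def mortality_trajectory(
    events: pd.DataFrame, trim_fraction: float = 0.05
) -> MortalityTrajectory:
    """Trimmed ln daily-death-probability trajectory for one cohort.

    All uncensored death events are sorted by day; the earliest and latest
    ``ceil(trim_fraction * D)`` events are excluded to suppress small-count
    noise in both tails. The retained events define the day window of the
    trajectory; within that window the daily death probability is
    deaths / at-risk over the flies still alive at the start of each day
    (censored flies count as at risk until their horizon).
    """
    censored = events["censored"].astype(bool).to_numpy()
    deaths = np.sort(events.loc[~censored, "death_day"].to_numpy())
    n_deaths = len(deaths)
    if n_deaths < 20:
        raise ValueError(f"need >= 20 deaths for trimming, got {n_deaths}")
    k = math.ceil(trim_fraction * n_deaths)
    kept = deaths[k : n_deaths - k]
    if len(kept) == 0:
        raise ValueError("trimming removed all events")
    day_lo, day_hi = kept[0], kept[-1]
    days, counts = np.unique(deaths, return_counts=True)
    all_exit = np.sort(events["death_day"].to_numpy())  # deaths and censoring
    at_risk = len(all_exit) - np.searchsorted(all_exit, days, side="left")
    in_window = (days >= day_lo) & (days <= day_hi)
    days, counts, at_risk = days[in_window], counts[in_window], at_risk[in_window]
    prob = counts / at_risk
    if (prob <= 0).any() or (at_risk <= 0).any():
        raise ValueError("nonpositive daily death probability or at-risk count")
    return MortalityTrajectory(
        days=days.astype(float),
        ln_daily_prob=np.log(prob),
        trim_fraction=trim_fraction,
    )


def fit_trajectory(traj: MortalityTrajectory) -> LinearFit:
    """Unweighted OLS of ln daily death probability on day (one point per day)."""
    if len(np.unique(traj.days)) < 2:
        raise ValueError("need >= 2 distinct days to fit a trajectory")
    res = stats.linregress(traj.days, traj.ln_daily_prob)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        r_squared=float(res.rvalue**2),
        n_points=len(traj.days),
    )


def displacement(
    traj_a: MortalityTrajectory,
    traj_b: MortalityTrajectory,
    mode: str = "paired",
) -> float:
    """Mean vertical offset (A minus B) between two mortality trajectories.

    ``paired`` (default): mean of ln-prob differences over days present in
    both trajectories. ``fitted``: mean difference between the two OLS fit
    lines evaluated over the union of observed days.
    """
    if mode == "paired":
        shared, ia, ib = np.intersect1d(traj_a.days, traj_b.days, return_indices=True)
        if len(shared) == 0:
            raise ValueError("no shared days between trajectories")
        return float(np.mean(traj_a.ln_daily_prob[ia] - traj_b.ln_daily_prob[ib]))
    if mode == "fitted":
        fa, fb = fit_trajectory(traj_a), fit_trajectory(traj_b)
        days = np.union1d(traj_a.days, traj_b.days)
        return float(np.mean(fa.predict(days) - fb.predict(days)))
    raise ValueError(f"unknown displacement mode: {mode!r}")


def accrual_rate(displacement_ln: float, window_days: float) -> float:
    """Daily gradient increase equivalent to a displacement accrued linearly
    over an exposure window of ``window_days`` days."""
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    return displacement_ln / window_days


def gradient_delta(fit_a: LinearFit, fit_b: LinearFit) -> float:
    """Difference in trajectory gradients (slope A minus slope B), day^-1."""
    return fit_a.slope - fit_b.slope


def combine_estimates(values: Iterable[float]) -> float:
    vals = list(values)
    if not vals:
        raise ValueError("no estimates to combine")
    return float(np.mean(vals))


def relative_excess(late: float, early: float) -> float:
    """Percent by which the late-life rate exceeds the early-life rate."""
    if early == 0:
        raise ValueError("early rate must be nonzero")
    return (late / early - 1.0) * 100.0


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (0.095 -> 0.10)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
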