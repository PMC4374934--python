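"""Cohort assembly, inclusion filtering and nonparametric statistics.

Conventions mirror the study design this pipeline serves: animals enter
the cohort only if the treated eye's intraocular pressure peaked above
25 mmHg within 48 h of laser treatment; group values are reported as
mean ± sample SD; two groups are compared with Mann–Whitney (exact by
full enumeration at the small group sizes typical of these cohorts),
more than two with Kruskal–Wallis; percentages quoted in results are
computed from group means and rounded half-up to the nearest integer.
No multiple-testing correction is applied by default (α = 0.05 per
comparison); Holm adjustment is available but off by default.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "filter_by_iop",
    "iop_peaks",
    "group_summary",
    "percent_loss",
    "survival_fraction",
    "gcl_decomposition",
    "mann_whitney",
    "kruskal_wallis",
    "correlation_r2",
    "holm_adjust",
    "round_half_up",
]

ALPHA = 0.05
EXACT_MAX_N = 16  # full enumeration up to n1 + n2 = 16


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero-upward."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    n_per_group: tuple
    method: str = "exact"
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


# ---------------------------------------------------------------- cohort


def iop_peaks(iop: pd.DataFrame, window_h: float = 48.0) -> pd.Series:
    """Per-animal treated-eye IOP peak within the first ``window_h``
    hours; animals with no in-window reading get NaN."""
    required = {"animal_id", "time_h", "iop_mmHg"}
    missing = required - set(iop.columns)
    if missing:
        raise ValueError(f"missing IOP columns: {sorted(missing)}")
    df = iop
    if "eye" in df.columns:
        df = df[df["eye"] == "LE"]
    df = df[df["time_h"] <= window_h]
    return df.groupby("animal_id")["iop_mmHg"].max()


def filter_by_iop(
    cohort: pd.DataFrame,
    iop: pd.DataFrame | pd.Series,
    threshold_mmHg: float = 25.0,
    window_h: float = 48.0,
):
    """Apply the hypertension inclusion rule.

    Retains animals whose treated-eye IOP peak is *strictly greater*
    than ``threshold_mmHg`` within the first ``window_h`` hours.
    ``iop`` is either a tonometry table or a precomputed per-animal peak
    Series.  Returns ``(filtered_cohort, exclusion_log)`` where the log
    lists each excluded animal with its reason.
    """
    peaks = iop if isinstance(iop, pd.Series) else iop_peaks(iop, window_h)
    exclusions = []
    keep = []
    for animal in cohort["animal_id"].unique():
        if animal not in peaks.index or pd.isna(peaks.loc[animal]):
            exclusions.append({"animal_id": animal, "reason": "no IOP record in window"})
        elif peaks.loc[animal] <= threshold_mmHg:
            exclusions.append(
                {
                    "animal_id": animal,
                    "reason": f"IOP peak {peaks.loc[animal]:.1f} mmHg "
                    f"not > {threshold_mmHg:g} mmHg within {window_h:g} h",
                }
            )
        else:
            keep.append(animal)
    return cohort[cohort["animal_id"].isin(keep)].reset_index(drop=True), exclusions


def group_summary(cohort: pd.DataFrame, grouping, value_col: str = "value") -> pd.DataFrame:
    """Mean ± sample SD (n−1 denominator) per group.

    Singleton groups report SD 0 with ``n = 1`` flagged by the ``n``
    column; empty input is an error.
    """
    if len(cohort) == 0:
        raise ValueError("cannot summarise an empty cohort")
    if isinstance(grouping, str):
        grouping = [grouping]

    def _agg(g):
        v = g[value_col].to_numpy(dtype=float)
        return pd.Series(
            {
                "mean": v.mean(),
                "sd": v.std(ddof=1) if v.size > 1 else 0.0,
                "n": v.size,
            }
        )

    out = cohort.groupby(grouping, sort=False).apply(_agg, include_groups=False).reset_index()
    out["n"] = out["n"].astype(int)
    return out


# ------------------------------------------------------- loss arithmetic


def percent_loss(control_mean: float, treated_mean: float):
    """Percent of the control population lost, from group means.

    Returns ``(raw, rounded)``: ``100 * (1 - treated/control)`` and its
    half-up integer rounding.
    """
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    raw = 100.0 * (1.0 - treated_mean / control_mean)
    return raw, round_half_up(raw)


def survival_fraction(control_mean: float, treated_mean: float):
    """Percent of the control population surviving: 100*treated/control."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    raw = 100.0 * treated_mean / control_mean
    return raw, round_half_up(raw)


def gcl_decomposition(dapi_mean: float, brn3a_mean: float) -> float:
    """Non-RGC nucleus count of the ganglion cell layer: DAPI − Brn3a.

    A negative result (more RGCs than nuclei) is flagged with a warning
    but returned as-is.
    """
    diff = dapi_mean - brn3a_mean
    if diff < 0:
        warnings.warn("Brn3a count exceeds DAPI nucleus count", stacklevel=2)
    return diff


# --------------------------------------------------------- rank tests


def _rank_sum_distribution_no_ties(n1: int, n: int) -> np.ndarray:
    """counts[s] = number of n1-subsets of ranks 1..n with rank sum s
    (dynamic programming over the Gaussian-binomial recurrence)."""
    max_sum = n * (n + 1) // 2
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=np.int64)
    dp[0, 0] = 1
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            dp[k, r:] += dp[k - 1, : max_sum + 1 - r]
    return dp[n1]


def mann_whitney(group_a, group_b, alternative: str = "two-sided") -> TestResult:
    """Mann–Whitney U test for two independent groups.

    The p-value is exact — from the full null distribution of the rank
    sum over all C(n1+n2, n1) group assignments — whenever
    ``n1 + n2 <= 16`` (the group sizes typical of these cohorts), with
    midranks handling ties; larger samples fall back to the normal
    approximation with tie correction.  Two-sided exact p doubles the
    smaller tail (capped at 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs at least one observation")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0

    if np.ptp(pooled) == 0:
        warnings.warn("all observations tied; p-value is 1", stacklevel=2)
        return TestResult(u1, 1.0, "Mann–Whitney U", (n1, n2), method="degenerate")

    if n1 + n2 <= EXACT_MAX_N:
        has_ties = np.unique(pooled).size != pooled.size
        eps = 1e-9
        if not has_ties:
            counts = _rank_sum_distribution_no_ties(n1, n1 + n2)
            total = counts.sum()
            sums = np.arange(counts.size, dtype=float)
            p_le = counts[sums <= r1 + eps].sum() / total
            p_ge = counts[sums >= r1 - eps].sum() / total
        else:
            sums = np.fromiter(
                (ranks[list(c)].sum() for c in itertools.combinations(range(n1 + n2), n1)),
                dtype=float,
            )
            total = sums.size
            p_le = float(np.count_nonzero(sums <= r1 + eps)) / total
            p_ge = float(np.count_nonzero(sums >= r1 - eps)) / total
        if alternative == "two-sided":
            p = min(1.0, 2.0 * min(p_le, p_ge))
        elif alternative == "greater":  # A tends larger than B
            p = p_ge
        else:
            p = p_le
        return TestResult(u1, float(p), "Mann–Whitney U", (n1, n2), method="exact")

    res = sps.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return TestResult(float(res.statistic), float(res.pvalue), "Mann–Whitney U",
                      (n1, n2), method="asymptotic")


def kruskal_wallis(groups) -> TestResult:
    """Kruskal–Wallis H test (tie-corrected, chi-square p on k−1 df)
    for three or more groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("Kruskal–Wallis requires at least 3 groups; use mann_whitney for 2")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return TestResult(0.0, 1.0, "Kruskal–Wallis H", tuple(g.size for g in groups),
                          method="degenerate")
    h, p = sps.kruskal(*groups)
    return TestResult(float(h), float(p), "Kruskal–Wallis H",
                      tuple(g.size for g in groups), method="chi-square")


# -------------------------------------------------------- correlation


@dataclass(frozen=True)
class CorrelationResult:
    r_squared: float
    slope: float
    intercept: float
    n: int


def correlation_r2(x_counts, y_counts) -> CorrelationResult:
    """Squared Pearson correlation (with regression line) between two
    paired per-retina count vectors."""
    x = np.asarray(x_counts, dtype=float)
    y = np.asarray(y_counts, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors; r² undefined")
    res = sps.linregress(x, y)
    return CorrelationResult(
        r_squared=float(res.rvalue**2),
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=int(x.size),
    )


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment (optional; the pipeline default applies
    no multiple-testing correction)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty_like(p)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj
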