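"""Developmental staging and the associated non-parametric statistics.

Staging clusters the central L2 cell volume — a quantity that grows
monotonically through development — with globally optimal 1D k-means
(dynamic programming over contiguous partitions of the sorted values;
deterministic, unlike seeded Lloyd iteration). The number of stages is
suggested by the elbow of the within-cluster-sum-of-squares (WSS) curve.
Group comparisons use Mann–Whitney U, division-frequency contrasts use
Fisher's exact test, and three-class distribution shifts use a χ² test.
No multiple-testing correction is applied across the summary grid; raw
p-values are reported.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("primordium3d")


@dataclass
class StageModel:
    """Result of staging by 1D clustering of central-cell volumes."""

    k: int
    means: np.ndarray              # cluster means, µm³, strictly increasing
    assignments: np.ndarray        # stage per organ: 1..k (0 = excluded)
    wss_curve: np.ndarray | None = None   # WSS over k = 1..k_max
    suggested_k: int | None = None
    low_confidence: bool = False

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        if np.any(np.diff(self.means) <= 0):
            raise ValueError("cluster means must be strictly increasing")


@dataclass
class TestResult:
    """A named statistical test outcome with its significance code."""

    name: str
    statistic: float
    p_value: float
    n_per_group: tuple
    flag: str | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    @property
    def code(self) -> str:
        return significance_code(self.p_value)


def significance_code(p: float) -> str:
    """Standard star ladder: *<0.05, **<0.01, ***<0.001, ****<0.0001."""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# optimal 1D k-means by dynamic programming

def kmeans_1d(values, k: int):
    """Globally optimal 1D k-means (contiguous-partition dynamic program).

    Returns (assignments, means, wss): assignments are 0-based cluster
    indices in the original input order, clusters ordered by ascending
    mean. O(k n²); deterministic.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of values ({n})")
    order = np.argsort(values, kind="stable")
    x = values[order]
    pre = np.concatenate([[0.0], np.cumsum(x)])
    pre2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_cost(i, j):  # cost of x[i:j], j exclusive
        s = pre[j] - pre[i]
        s2 = pre2[j] - pre2[i]
        m = j - i
        return s2 - s * s / m

    # dp[c][j] = min WSS of x[:j] into c clusters
    dp = np.full((k + 1, n + 1), np.inf)
    back = np.zeros((k + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = np.inf, c - 1
            for i in range(c - 1, j):
                cost = dp[c - 1, i] + seg_cost(i, j)
                if cost < best:
                    best, arg = cost, i
            dp[c, j] = best
            back[c, j] = arg
    # backtrack boundaries
    bounds = [n]
    j = n
    for c in range(k, 0, -1):
        j = back[c, j]
        bounds.append(j)
    bounds = bounds[::-1]
    assign_sorted = np.empty(n, dtype=int)
    means = []
    for c in range(k):
        i, j = bounds[c], bounds[c + 1]
        assign_sorted[i:j] = c
        means.append(x[i:j].mean())
    assignments = np.empty(n, dtype=int)
    assignments[order] = assign_sorted
    return assignments, np.asarray(means), float(dp[k, n])


def wss_curve_and_elbow(values, k_max: int = 8,
                        log_scale: bool = False) -> StageModel:
    """WSS over k = 1..k_max and the elbow-suggested cluster count.

    The suggestion is the k maximizing the normalized (logarithmic) second
    difference of the WSS curve — the discrete curvature of the elbow plot
    on a scale-free axis. Cell volumes grow geometrically across stages,
    so successive WSS drops span orders of magnitude and a linear second
    difference would always bend hardest at k = 2; the log curvature peaks
    where the curve genuinely flattens. A suggestion whose curvature is
    small (< 0.8) is flagged low-confidence (near-flat elbow: likely a
    single cluster).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 values")
    k_max = min(k_max, n)
    fit_values = np.log(values) if log_scale else values
    wss = np.array([kmeans_1d(fit_values, k)[2] for k in range(1, k_max + 1)])
    floor = max(wss[0], 1e-300) * 1e-12
    logw = np.log(np.maximum(wss, floor))
    drops = {k: logw[k - 2] - logw[k - 1] for k in range(2, k_max + 1)}
    curv = {k: logw[k - 2] - 2 * logw[k - 1] + logw[k]
            for k in range(2, k_max)}
    if drops:
        # splitting out a real cluster shrinks the log-WSS by a large step;
        # once only noise is being split, the steps collapse. The elbow is
        # the deepest k whose step is still comparable (>= 60%) to the
        # largest one — robust to the double bends that hierarchically
        # spaced volumes produce
        dmax = max(drops.values())
        candidates = [k for k, v in drops.items() if v >= 0.6 * dmax]
        suggested = max(candidates) if candidates else min(drops)
        # an unclustered (single-blob) sample yields log-WSS curvature of
        # about 0.6 at k=2 from the k^-2 decay alone; flag anything near it
        cmax = max(curv.values()) if curv else 0.0
        low_conf = cmax < 0.8
    else:
        suggested, low_conf = 1, True
    assignments, _, _ = kmeans_1d(fit_values, suggested)
    means = np.array([values[assignments == c].mean()
                      for c in range(suggested)])
    return StageModel(
        k=suggested, means=means, assignments=assignments + 1,
        wss_curve=wss, suggested_k=suggested, low_confidence=low_conf,
    )


def assign_stages(values, k: int, stage0_mask=None,
                  log_scale: bool = False) -> StageModel:
    """Stage organs 1..k by optimal 1D k-means of central-cell volumes.

    Organs flagged in ``stage0_mask`` (floret meristems) are excluded from
    the fit and assigned stage 0. Stages are numbered by ascending cluster
    mean; the result is deterministic and independent of input order.

    With ``log_scale`` the partition is found on log-volumes — the natural
    scale for a quantity that roughly doubles per stage, and far more
    robust when cluster dispersion grows with the mean — while the
    reported cluster means stay arithmetic (µm³).
    """
    values = np.asarray(values, dtype=float)
    if stage0_mask is None:
        stage0_mask = np.zeros(len(values), dtype=bool)
    stage0_mask = np.asarray(stage0_mask, dtype=bool)
    keep = ~stage0_mask
    if k > keep.sum():
        raise ValueError(f"k={k} exceeds the {keep.sum()} non-excluded organs")
    fit_values = np.log(values[keep]) if log_scale else values[keep]
    assign, _, wss = kmeans_1d(fit_values, k)
    means = np.array([values[keep][assign == c].mean() for c in range(k)])
    stages = np.zeros(len(values), dtype=int)
    stages[keep] = assign + 1
    return StageModel(k=k, means=means, assignments=stages)


# ---------------------------------------------------------------------------
# tests

def mann_whitney_u(x, y, seed: int = 0, n_permutations: int = 20000) -> TestResult:
    """Two-sided Mann–Whitney U test with midrank ties.

    Exact p by full enumeration for tie-free samples with n_x+n_y ≤ 20;
    seeded permutation p (≥ 20,000 resamples) for small tied samples;
    normal approximation with tie and continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    n_tot = len(pooled)
    if not has_ties and n_tot <= 20:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        flag = "exact"
    elif has_ties and n_tot <= 30:
        method = sps.PermutationMethod(
            n_resamples=n_permutations, rng=np.random.default_rng(seed)
        )
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        flag = "permutation"
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        flag = "asymptotic"
    return TestResult("mann_whitney_u", float(res.statistic),
                      float(min(res.pvalue, 1.0)), (len(x), len(y)), flag=flag)


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test on a 2×2 count table.

    The two-sided p sums hypergeometric probabilities of all tables with
    the observed margins whose point probability does not exceed the
    observed one. A zero margin yields p = 1 with a flag.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("need a 2x2 table of non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return TestResult("fisher_exact", np.nan, 1.0,
                          tuple(table.sum(axis=1)), flag="zero_margin")
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return TestResult("fisher_exact", float(odds), float(p),
                      tuple(table.sum(axis=1)))


def chi_square_contingency(observed) -> TestResult:
    """Pearson χ² test of independence (no continuity correction)."""
    observed = np.asarray(observed, dtype=float)
    total = observed.sum()
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / total
    if np.any(expected <= 0):
        raise ValueError(
            "expected count of zero: merge classes before testing"
        )
    stat, p, dof, _ = sps.chi2_contingency(observed, correction=False)
    return TestResult("chi_square", float(stat), float(p),
                      tuple(int(v) for v in observed.sum(axis=1)),
                      flag=f"df={dof}")


def bin_three_classes(values_a, values_b) -> np.ndarray:
    """2×3 contingency table with class boundaries at pooled tertiles."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    pooled = np.concatenate([a, b])
    if len(pooled) < 6:
        raise ValueError("need at least 6 pooled values for tertile classes")
    q1, q2 = np.quantile(pooled, [1 / 3, 2 / 3])
    if q1 == q2:
        raise ValueError("degenerate tertiles (massive ties); classes undefined")
    def counts(v):
        return [int(np.sum(v <= q1)),
                int(np.sum((v > q1) & (v <= q2))),
                int(np.sum(v > q2))]
    return np.array([counts(a), counts(b)])


def group_summary(
    cell_table: pd.DataFrame,
    value_col: str = "volume_um3",
    class_col: str = "contact_class",
    stage_col: str = "stage",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-(cell class × stage) summary with consecutive-stage tests.

    Columns: mean, SEM (= sd/√n), n, and for each stage after the first
    within a class the Mann–Whitney p against the previous stage plus its
    significance code. Groups with n < 2 carry no SEM and skip the test.
    """
    df = cell_table.dropna(subset=[value_col, stage_col]).copy()
    df[stage_col] = df[stage_col].astype(int)
    rows = []
    for cls, sub in df.groupby(class_col, sort=True):
        stages = sorted(sub[stage_col].unique())
        prev_values = None
        prev_stage = None
        for st in stages:
            v = sub.loc[sub[stage_col] == st, value_col].to_numpy()
            row = {
                class_col: cls, stage_col: st, "n": len(v),
                "mean": float(np.mean(v)),
                "sem": float(np.std(v, ddof=1) / np.sqrt(len(v)))
                       if len(v) >= 2 else np.nan,
                "p_vs_prev": np.nan, "code": "", "flag": "",
            }
            if len(v) < 2:
                row["flag"] = "n<2: SEM absent, test skipped"
            elif prev_values is not None and len(prev_values) >= 2:
                res = mann_whitney_u(prev_values, v, seed=seed)
                row["p_vs_prev"] = res.p_value
                row["code"] = res.code
                row["flag"] = f"vs stage {prev_stage} ({res.flag})"
            prev_values, prev_stage = v, st
            rows.append(row)
    return pd.DataFrame(rows)
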