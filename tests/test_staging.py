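"""Optimal 1D clustering, elbow selection and the non-parametric tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from primordium3d.staging import (
    assign_stages,
    bin_three_classes,
    chi_square_contingency,
    fisher_exact_2x2,
    group_summary,
    kmeans_1d,
    mann_whitney_u,
    significance_code,
    wss_curve_and_elbow,
)


# ---------------------------------------------------------------------------
# 1D k-means

def test_two_cluster_exact_split():
    values = np.array([1.0, 1.1, 0.9, 5.0, 5.2, 4.8]) * 1e3
    model = assign_stages(values, k=2)
    np.testing.assert_allclose(model.means, [1000.0, 5000.0])
    assert (model.assignments == 1).sum() == 3
    assert (model.assignments == 2).sum() == 3


def test_kmeans_order_invariance():
    rng = np.random.default_rng(0)
    values = rng.uniform(0, 10, 20)
    a1, m1, w1 = kmeans_1d(values, 3)
    perm = rng.permutation(20)
    a2, m2, w2 = kmeans_1d(values[perm], 3)
    np.testing.assert_allclose(m1, m2)
    np.testing.assert_array_equal(a1[perm], a2)


def test_dp_beats_seeded_lloyd():
    """Global optimality: the DP WSS never exceeds Lloyd from 100 seeds."""
    rng = np.random.default_rng(1)
    for _ in range(50):
        n = int(rng.integers(8, 30))
        k = int(rng.integers(2, 5))
        values = rng.normal(size=n) * rng.uniform(1, 10)
        _, _, wss_dp = kmeans_1d(values, k)
        best_lloyd = np.inf
        for seed in range(100):
            r = np.random.default_rng(seed)
            centers = r.choice(values, k, replace=False)
            for _ in range(50):
                assign = np.argmin(np.abs(values[:, None] - centers), axis=1)
                new = np.array([values[assign == c].mean()
                                if (assign == c).any() else centers[c]
                                for c in range(k)])
                if np.allclose(new, centers):
                    break
                centers = new
            wss = sum(((values[assign == c] - values[assign == c].mean()) ** 2).sum()
                      for c in range(k) if (assign == c).any())
            best_lloyd = min(best_lloyd, wss)
        assert wss_dp <= best_lloyd + 1e-9


def test_wss_monotone_nonincreasing():
    rng = np.random.default_rng(2)
    values = rng.uniform(0, 100, 25)
    model = wss_curve_and_elbow(values, k_max=8)
    assert np.all(np.diff(model.wss_curve) <= 1e-9)


def test_elbow_recovers_planted_k4():
    rng = np.random.default_rng(3)
    sigma = np.sqrt(np.log(1.01))
    values = np.concatenate([
        m * np.exp(rng.normal(-sigma**2 / 2, sigma, 10))
        for m in (500, 1000, 2000, 4000)
    ])
    model = wss_curve_and_elbow(values, k_max=8, log_scale=True)
    assert model.suggested_k == 4
    assert not model.low_confidence


def test_single_cluster_flagged_low_confidence():
    rng = np.random.default_rng(4)
    values = 1000 * np.exp(rng.normal(0, 0.05, 30))
    model = wss_curve_and_elbow(values, k_max=8, log_scale=True)
    assert model.low_confidence


def test_stage0_exclusion():
    values = np.array([50.0, 60.0, 1000.0, 1100.0, 5000.0, 5100.0])
    mask = np.array([True, True, False, False, False, False])
    model = assign_stages(values, k=2, stage0_mask=mask)
    assert list(model.assignments[:2]) == [0, 0]
    assert set(model.assignments[2:]) == {1, 2}


def test_k_exceeding_organs_errors():
    with pytest.raises(ValueError):
        assign_stages(np.array([1.0, 2.0]), k=3)


# ---------------------------------------------------------------------------
# Mann-Whitney

def _brute_force_mw_p(x, y):
    """Exact two-sided p by full enumeration of group labelings."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = sps.rankdata(pooled)
    u_obs = sps.mannwhitneyu(x, y, alternative="two-sided").statistic
    nx, ny = len(x), len(y)
    u_obs = max(u_obs, nx * ny - u_obs)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        r = ranks[list(combo)].sum()
        u = r - n * (n + 1) / 2
        u = max(u, nx * ny - u)
        total += 1
        if u >= u_obs - 1e-9:
            count += 1
    return count / total


def test_mann_whitney_textbook_case():
    res = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert min(res.statistic, 9 - res.statistic) == pytest.approx(0.0)
    assert res.p_value == pytest.approx(0.1)


def test_mann_whitney_symmetry():
    res1 = mann_whitney_u([1, 2, 3], [4, 5, 6])
    res2 = mann_whitney_u([4, 5, 6], [1, 2, 3])
    assert res1.p_value == pytest.approx(res2.p_value)


@pytest.mark.parametrize("nx,ny", [(2, 3), (3, 3), (4, 4), (3, 6), (5, 5)])
def test_mann_whitney_exact_matches_enumeration(nx, ny):
    rng = np.random.default_rng(nx * 10 + ny)
    for _ in range(3):
        pooled = rng.permutation(np.arange(1.0, nx + ny + 1))  # tie-free
        x, y = pooled[:nx], pooled[nx:]
        res = mann_whitney_u(x, y)
        assert res.flag == "exact"
        assert res.p_value == pytest.approx(_brute_force_mw_p(x, y))


def test_mann_whitney_asymptotic_close_to_exact():
    rng = np.random.default_rng(9)
    x = rng.normal(0, 1, 10)
    y = rng.normal(0.5, 1, 10)
    exact = mann_whitney_u(x, y)
    assert exact.flag == "exact"
    approx = sps.mannwhitneyu(x, y, alternative="two-sided",
                              method="asymptotic")
    assert abs(exact.p_value - approx.pvalue) < 0.01


def test_mann_whitney_empty_errors():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# Fisher

def _brute_force_fisher_p(table):
    """Two-sided p by hypergeometric enumeration over all fixed-margin tables."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    probs = {}
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[aa] = sps.hypergeom.pmf(aa, n, r1, c1)
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


def test_fisher_diagonal_example():
    res = fisher_exact_2x2([[3, 0], [0, 3]])
    assert res.p_value == pytest.approx(0.1)


def test_fisher_uniform_table():
    assert fisher_exact_2x2([[1, 1], [1, 1]]).p_value == pytest.approx(1.0)


def test_fisher_matches_enumeration_small_margins():
    rng = np.random.default_rng(5)
    for _ in range(20):
        table = rng.integers(0, 8, (2, 2))
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            continue
        res = fisher_exact_2x2(table)
        assert res.p_value == pytest.approx(_brute_force_fisher_p(table),
                                            abs=1e-9)


def test_fisher_invariances():
    table = np.array([[5, 2], [1, 7]])
    p = fisher_exact_2x2(table).p_value
    assert fisher_exact_2x2(table.T).p_value == pytest.approx(p)
    assert fisher_exact_2x2(table[::-1]).p_value == pytest.approx(p)
    assert fisher_exact_2x2(table[:, ::-1]).p_value == pytest.approx(p)


def test_fisher_zero_margin_flagged():
    res = fisher_exact_2x2([[0, 0], [3, 5]])
    assert res.p_value == 1.0 and res.flag == "zero_margin"


# ---------------------------------------------------------------------------
# chi-square and class binning

def test_chi_square_uniform():
    res = chi_square_contingency([[10, 10, 10], [10, 10, 10]])
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_chi_square_closed_form_df2():
    res = chi_square_contingency([[20, 10, 0], [0, 10, 20]])
    assert res.statistic == pytest.approx(40.0)
    assert res.p_value == pytest.approx(np.exp(-20.0), rel=1e-6)


def test_chi_square_column_permutation_invariance():
    obs = np.array([[12, 5, 3], [4, 9, 7]])
    base = chi_square_contingency(obs).statistic
    for perm in itertools.permutations(range(3)):
        assert chi_square_contingency(obs[:, perm]).statistic == \
            pytest.approx(base)


def test_chi_square_zero_expected_errors():
    with pytest.raises(ValueError, match="merge"):
        chi_square_contingency([[0, 5, 5], [0, 3, 7]])


def test_tertile_binning():
    table = bin_three_classes(np.arange(1, 10), np.arange(1, 10))
    np.testing.assert_array_equal(table, [[3, 3, 3], [3, 3, 3]])
    shifted = bin_three_classes(np.arange(1, 10), np.arange(1, 10) + 100.0)
    # pooled tertiles hold 6 values each; the top class is pure B and the
    # bottom class contains no B at all
    assert shifted[1, 2] == 6 and shifted[0, 2] == 0
    assert shifted[1, 0] == 0
    assert shifted.sum() == 18 and table.sum() == 18


def test_tertile_binning_degenerate_errors():
    with pytest.raises(ValueError, match="tertile"):
        bin_three_classes([1.0] * 5, [1.0] * 5)


# ---------------------------------------------------------------------------
# significance codes and group summary

def test_significance_code_ladder():
    assert significance_code(0.049) == "*"
    assert significance_code(0.051) == "ns"
    assert significance_code(0.009) == "**"
    assert significance_code(0.0009) == "***"
    assert significance_code(0.00009) == "****"


def test_group_summary_recovers_planted_means():
    rng = np.random.default_rng(6)
    rows = []
    for stage, mean in ((1, 500.0), (2, 1000.0), (3, 2000.0)):
        for _ in range(12):
            rows.append({"contact_class": "central_L2", "stage": stage,
                         "volume_um3": rng.normal(mean, mean * 0.1)})
    table = pd.DataFrame(rows)
    summary = group_summary(table)
    for stage, mean in ((1, 500.0), (2, 1000.0), (3, 2000.0)):
        row = summary[(summary.stage == stage)].iloc[0]
        assert row["mean"] == pytest.approx(mean, rel=0.10)
        assert row["n"] == 12
        assert np.isfinite(row["sem"])
    late = summary[summary.stage > 1]
    assert (late["p_vs_prev"] < 0.05).all()  # planted doubling is detectable


def test_group_summary_identical_groups_ns():
    rows = []
    for stage in (1, 2):
        for v in np.linspace(10, 20, 8):
            rows.append({"contact_class": "contact1", "stage": stage,
                         "volume_um3": v})
    summary = group_summary(pd.DataFrame(rows))
    row2 = summary[summary.stage == 2].iloc[0]
    assert row2["code"] == "ns"
    assert row2["p_vs_prev"] > 0.9


def test_group_summary_small_group_flagged():
    rows = [{"contact_class": "central_L3", "stage": 1, "volume_um3": 5.0}]
    summary = group_summary(pd.DataFrame(rows))
    assert "n<2" in summary.iloc[0]["flag"]
    assert np.isnan(summary.iloc[0]["sem"])
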