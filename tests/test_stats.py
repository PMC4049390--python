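import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lsepipe import stats as lst


# ------------------------------------------------------------------ Fisher --
def fisher_enumeration(a, b, c, d):
    """Exhaustive hypergeometric two-sided p: sum of table probabilities
    no larger than the observed one, at fixed margins."""
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def prob(x):
        return (
            math.comb(r1, x)
            * math.comb(n - r1, c1 - x)
            / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def test_fisher_trivial_equal_zero_successes():
    assert lst.fisher_exact_2x2(0, 10, 0, 10) == pytest.approx(1.0)


def test_fisher_small_table_matches_enumeration():
    assert lst.fisher_exact_2x2(2, 3, 1, 4) == pytest.approx(
        fisher_enumeration(2, 3, 1, 4), rel=1e-9
    )


@given(st.tuples(*[st.integers(0, 8)] * 4))
@settings(max_examples=60, deadline=None)
def test_fisher_matches_enumeration_property(table):
    a, b, c, d = table
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return
    assert lst.fisher_exact_2x2(a, b, c, d) == pytest.approx(
        fisher_enumeration(a, b, c, d), rel=1e-9
    )


@given(st.tuples(*[st.integers(0, 12)] * 4))
@settings(max_examples=40, deadline=None)
def test_fisher_symmetric_under_row_and_column_swap(table):
    a, b, c, d = table
    assert lst.fisher_exact_2x2(a, b, c, d) == pytest.approx(
        lst.fisher_exact_2x2(d, c, b, a), rel=1e-12
    )


def test_fisher_negative_counts_rejected():
    with pytest.raises(ValueError):
        lst.fisher_exact_2x2(-1, 2, 3, 4)


def test_fisher_by_size_category_frame():
    rows = [lst.SizeCategoryRow("clusters", 6, 24, 474, 0, 487)]
    out = lst.fisher_by_size_category(rows)
    assert out.loc[0, "p_value"] == pytest.approx(9.27e-8, rel=1e-2)


# ------------------------------------------------------------ Mann-Whitney --
def test_mann_whitney_identical_samples():
    _, p = lst.mann_whitney_omega([1, 2, 3, 4], [1, 2, 3, 4])
    assert p > 0.8


def test_mann_whitney_exact_enumeration_case():
    _, p = lst.mann_whitney_omega([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
    assert p == pytest.approx(0.1, abs=1e-12)
    # oracle: enumerate all C(6,3)=20 rank splits; only the two extreme
    # arrangements are as separated, so two-sided p = 2/20
    ranks = range(6)
    u_obs = 0  # group A occupies the three smallest ranks
    count = 0
    for combo in itertools.combinations(ranks, 3):
        u = sum(combo) - 3
        if min(u, 9 - u) <= min(u_obs, 9 - u_obs):
            count += 1
    assert count / 20 == pytest.approx(0.1)


def test_mann_whitney_empty_group():
    with pytest.raises(ValueError):
        lst.mann_whitney_omega([], [1.0])


def test_mann_whitney_detects_shift():
    rng = np.random.default_rng(0)
    hits = 0
    for _ in range(20):
        a = rng.normal(0.0, 1.0, 200)
        b = rng.normal(0.3, 1.0, 200)
        _, p = lst.mann_whitney_omega(a, b)
        hits += p < 0.05
    assert hits >= 15


# ------------------------------------------------------------------ window --
def _records(ds, omega):
    return pd.DataFrame({"dS": ds, "omega": omega})


def test_window_minimum_count_rule():
    rng = np.random.default_rng(1)
    a = _records(rng.uniform(0, 0.01, 99), rng.uniform(0, 1, 99))
    b = _records(rng.uniform(0, 0.01, 200), rng.uniform(0, 1, 200))
    out = lst.sliding_window_ds_test(a, b, min_per_group=100)
    assert out.empty


def test_window_partition_is_disjoint_and_covering():
    rng = np.random.default_rng(2)
    a = _records(rng.uniform(0, 0.05, 2000), rng.uniform(0, 1, 2000))
    b = _records(rng.uniform(0, 0.05, 2000), rng.uniform(0, 1, 2000))
    out = lst.sliding_window_ds_test(a, b, min_per_group=100)
    assert len(out) > 0
    # windows are consecutive, non-overlapping multiples of the width
    for _, row in out.iterrows():
        assert row["interval_hi"] == pytest.approx(row["interval_lo"] + 0.01)
        assert (row["interval_lo"] / 0.01) == pytest.approx(
            round(row["interval_lo"] / 0.01)
        )
    # every record of a tested window is counted exactly once
    total = out["nA"].sum()
    in_windows = sum(
        ((a["dS"] >= lo) & (a["dS"] < lo + 0.01)).sum()
        for lo in out["interval_lo"]
    )
    assert total == in_windows


def test_window_null_calibration():
    rng = np.random.default_rng(3)
    a = _records(rng.uniform(0, 0.3, 20000), rng.normal(0.5, 0.2, 20000))
    b = _records(rng.uniform(0, 0.3, 20000), rng.normal(0.5, 0.2, 20000))
    out = lst.sliding_window_ds_test(a, b, min_per_group=100)
    frac_sig = (out["p_value"] < 0.05).mean()
    assert frac_sig < 0.15  # ~5% expected under the null


def test_window_constructed_signal_localised():
    rng = np.random.default_rng(4)
    ds_a = rng.uniform(0, 0.15, 30000)
    omega_a = rng.normal(0.5, 0.1, 30000)
    boost = (ds_a >= 0.05) & (ds_a < 0.10)
    omega_a[boost] += 0.5
    a = _records(ds_a, omega_a)
    b = _records(rng.uniform(0, 0.15, 30000), rng.normal(0.5, 0.1, 30000))
    out = lst.sliding_window_ds_test(a, b, min_per_group=100)
    sig = out[out["p_value"] < 1e-4]
    assert not sig.empty
    assert ((sig["interval_lo"] >= 0.05) & (sig["interval_lo"] < 0.10)).all()


# ---------------------------------------------------------------- Spearman --
def test_spearman_monotonic():
    rho, _ = lst.spearman_clusters_vs_divergence([1, 2, 3, 4], [10, 20, 30, 40])
    assert rho == pytest.approx(1.0)
    rho, _ = lst.spearman_clusters_vs_divergence([4, 3, 2, 1], [10, 20, 30, 40])
    assert rho == pytest.approx(-1.0)


def test_spearman_needs_three_points():
    with pytest.raises(ValueError):
        lst.spearman_clusters_vs_divergence([1, 2], [1, 2])


def _average_ranks(x):
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    sx = np.asarray(x)[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i: j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def test_spearman_with_ties_matches_rank_formula():
    rng = np.random.default_rng(9)
    x = rng.integers(0, 5, 10).astype(float)
    y = rng.integers(0, 5, 10).astype(float)
    rho, _ = lst.spearman_clusters_vs_divergence(y, x)
    rx, ry = _average_ranks(x), _average_ranks(y)
    expected = np.corrcoef(rx, ry)[0, 1]
    assert rho == pytest.approx(expected, abs=1e-12)


# ----------------------------------------------------------------- summary --
def _branch_frame(omegas, cluster="c1"):
    return pd.DataFrame(
        {
            "cluster_id": cluster,
            "omega": omegas,
            "is_internal": False,
        }
    )


def test_summary_all_purifying():
    out = lst.summarize_branch_categories(
        _branch_frame([0.5] * 10), {"c1": "UP2"}
    )
    row = out.iloc[0]
    assert row["pct_lt1"] == 100.0
    assert row["mean_omega_lt1"] == pytest.approx(0.5)
    assert row["n_gt1"] == 0


def test_summary_percentages_sum_to_100():
    rng = np.random.default_rng(12)
    out = lst.summarize_branch_categories(
        _branch_frame(rng.lognormal(-0.5, 0.7, 500)), {"c1": "UP2"}
    )
    row = out.iloc[0]
    assert row["pct_lt1"] + row["pct_gt1"] == pytest.approx(100.0)
    assert row["n_gt1_2"] <= row["n_gt1"]


def test_summary_matches_brute_force_recomputation():
    rng = np.random.default_rng(13)
    om = rng.lognormal(-0.5, 0.8, 300)
    out = lst.summarize_branch_categories(_branch_frame(om), {"c1": "SO2"})
    row = out.iloc[0]
    assert row["n_branches"] == 300
    assert row["mean_omega"] == pytest.approx(om.mean())
    assert row["se_omega"] == pytest.approx(om.std(ddof=1) / np.sqrt(300))
    assert row["pct_gt1_2"] == pytest.approx(100.0 * (om > 1.2).mean())
    assert row["mean_omega_gt1"] == pytest.approx(om[om > 1.0].mean())
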