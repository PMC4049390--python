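"""Comparative statistics: Fisher tests by cluster-size category,
Mann-Whitney omega comparisons, sliding-window dS tests, Spearman
correlation and the category summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

WINDOW_WIDTH = 0.01
WINDOW_MIN_PER_GROUP = 100  # methods default; 25 offered as an alternative


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]]."""
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be nonnegative")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


@dataclass
class SizeCategoryRow:
    unit: str  # clusters | codons | branches
    size: int
    up_under: int
    up_not: int
    so_under: int
    so_not: int
    p_value: float = np.nan


def fisher_by_size_category(rows: list[SizeCategoryRow]) -> pd.DataFrame:
    out = []
    for r in rows:
        p = fisher_exact_2x2(r.up_under, r.up_not, r.so_under, r.so_not)
        out.append(
            {
                "unit": r.unit,
                "size": r.size,
                "up_under": r.up_under,
                "up_not": r.up_not,
                "so_under": r.so_under,
                "so_not": r.so_not,
                "p_value": p,
            }
        )
    return pd.DataFrame(out)


def mann_whitney_omega(a, b, exact_max_n: int = 20):
    """Two-sided Mann-Whitney U; exact enumeration for small tie-free
    samples, normal approximation with tie correction otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    small = max(a.size, b.size) <= exact_max_n
    method = "exact" if (no_ties and small) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class WindowResult:
    lo: float
    hi: float
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float


def sliding_window_ds_test(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    width: float = WINDOW_WIDTH,
    min_per_group: int = WINDOW_MIN_PER_GROUP,
) -> pd.DataFrame:
    """Mann-Whitney on omega within consecutive dS windows of `width`.

    Windows are [k*width, (k+1)*width) starting at 0; a test is emitted
    only when both groups contribute at least `min_per_group` records.
    """
    out = []
    ds_max = 0.0
    for df in (records_a, records_b):
        if len(df):
            ds_max = max(ds_max, float(df["dS"].max()))
    n_windows = int(np.floor(ds_max / width)) + 1 if ds_max > 0 else 0
    for k in range(n_windows):
        lo, hi = k * width, (k + 1) * width
        wa = records_a[(records_a["dS"] >= lo) & (records_a["dS"] < hi)]
        wb = records_b[(records_b["dS"] >= lo) & (records_b["dS"] < hi)]
        if len(wa) < min_per_group or len(wb) < min_per_group:
            continue
        u, p = mann_whitney_omega(wa["omega"].to_numpy(), wb["omega"].to_numpy())
        out.append(
            {
                "interval_lo": lo,
                "interval_hi": hi,
                "nA": len(wa),
                "nB": len(wb),
                "U": u,
                "p_value": p,
            }
        )
    return pd.DataFrame(
        out, columns=["interval_lo", "interval_hi", "nA", "nB", "U", "p_value"]
    )


def spearman_clusters_vs_divergence(counts, divergence_times):
    """Spearman rank correlation (with ties) and its two-sided p."""
    counts = np.asarray(counts, dtype=float)
    divergence_times = np.asarray(divergence_times, dtype=float)
    if counts.size != divergence_times.size:
        raise ValueError("paired observations required")
    if counts.size < 3:
        raise ValueError("need at least 3 paired observations")
    rho, p = sps.spearmanr(divergence_times, counts)
    return float(rho), float(p)


def summarize_branch_categories(
    branches: pd.DataFrame, category_of_cluster: dict[str, str]
) -> pd.DataFrame:
    """Per-category branch summary mirroring the branch-analysis table.

    One row per category with branch counts and percentages/means for the
    omega < 1, omega > 1 and omega > 1.2 strata plus mean omega +/- SE.
    """
    df = branches.copy()
    df["category"] = df["cluster_id"].map(category_of_cluster)
    rows = []
    for cat, grp in df.groupby("category", sort=True):
        om = grp["omega"].to_numpy(dtype=float)
        n = om.size
        lt1 = om <= 1.0
        gt1 = om > 1.0
        gt12 = om > 1.2
        rows.append(
            {
                "category": cat,
                "n_branches": n,
                "n_lt1": int(lt1.sum()),
                "pct_lt1": 100.0 * lt1.mean() if n else np.nan,
                "mean_omega_lt1": om[lt1].mean() if lt1.any() else np.nan,
                "n_gt1": int(gt1.sum()),
                "pct_gt1": 100.0 * gt1.mean() if n else np.nan,
                "mean_omega_gt1": om[gt1].mean() if gt1.any() else np.nan,
                "n_gt1_2": int(gt12.sum()),
                "pct_gt1_2": 100.0 * gt12.mean() if n else np.nan,
                "mean_omega_gt1_2": om[gt12].mean() if gt12.any() else np.nan,
                "mean_omega": om.mean() if n else np.nan,
                "se_omega": om.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _median_quartiles(values) -> str:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return "NA"
    med = np.median(values)
    q1, q3 = np.percentile(values, [25, 75])
    return f"{med:g} ({q1:g}; {q3:g})"


def summarize_dataset(
    clusters: pd.DataFrame,
    branches: pd.DataFrame,
) -> pd.DataFrame:
    """Per-category dataset accounting: cluster counts, median (quartile)
    cluster size and alignment length, total sites and branches."""
    rows = []
    for cat, grp in clusters.groupby("category", sort=True):
        cat_branches = branches[branches["cluster_id"].isin(grp["cluster_id"])]
        rows.append(
            {
                "category": cat,
                "n_clusters": len(grp),
                "median_cluster_size": _median_quartiles(grp["size"]),
                "median_alignment_length_bp": _median_quartiles(
                    grp["alignment_length_bp"]
                )
                if "alignment_length_bp" in grp
                else "NA",
                "total_sites": int(grp["n_codons"].sum())
                if "n_codons" in grp
                else 0,
                "n_branches": len(cat_branches),
            }
        )
    return pd.DataFrame(rows)


def build_size_category_rows(
    clusters: pd.DataFrame,
    branches: pd.DataFrame,
    sizes=range(4, 11),
) -> list[SizeCategoryRow]:
    """Assemble the 2x2 inputs (clusters / codons / branches) per size."""
    rows: list[SizeCategoryRow] = []
    is_up = clusters["category"].astype("string").str.startswith("UP")
    for size in sizes:
        sel = clusters["size"] == size
        up = clusters[sel & is_up]
        so = clusters[sel & ~is_up]
        if up.empty and so.empty:
            continue
        rows.append(
            SizeCategoryRow(
                unit="clusters",
                size=size,
                up_under=int(up["under_selection"].sum()),
                up_not=int((~up["under_selection"].astype(bool)).sum()),
                so_under=int(so["under_selection"].sum()),
                so_not=int((~so["under_selection"].astype(bool)).sum()),
            )
        )
        up_codons = int(up["n_codons"].sum())
        so_codons = int(so["n_codons"].sum())
        up_flagged = int(up["n_flagged_sites"].sum())
        so_flagged = int(so["n_flagged_sites"].sum())
        rows.append(
            SizeCategoryRow(
                unit="codons",
                size=size,
                up_under=up_flagged,
                up_not=up_codons - up_flagged,
                so_under=so_flagged,
                so_not=so_codons - so_flagged,
            )
        )
        up_br = branches[branches["cluster_id"].isin(up["cluster_id"])]
        so_br = branches[branches["cluster_id"].isin(so["cluster_id"])]
        rows.append(
            SizeCategoryRow(
                unit="branches",
                size=size,
                up_under=int((up_br["omega"] > 1.2).sum()),
                up_not=int((up_br["omega"] <= 1.2).sum()),
                so_under=int((so_br["omega"] > 1.2).sum()),
                so_not=int((so_br["omega"] <= 1.2).sum()),
            )
        )
    return rows
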