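"""Subject-level cohort statistics for DDI/VDP studies.

Operates on a tidy table with one row per subject: group and category
labels, slice orientation, the imaging metrics (mean DDI, VDP, DDI/VDP) and
optional percent-predicted pulmonary function tests (FEV1, FVC, FEV1/FVC).

The analysis layer mirrors common practice for imaging-biomarker cohorts:
per-group Pearson correlations between metrics and PFTs (pairwise-complete),
Kruskal-Wallis omnibus tests across groups with *unadjusted* pairwise
p-values compared against a Bonferroni-adjusted significance threshold
(0.05/9 across the nine disease groups, 0.05/4 across the four disease
categories), and a two-tailed t-test comparing axial vs coronal
acquisitions within a group.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

METRICS = ("mean_ddi", "vdp_percent", "ddi_over_vdp")
PFT_COLUMNS = ("fev1", "fvc", "fev1_fvc")

N_GROUP_COMPARISONS = 9
N_CATEGORY_COMPARISONS = 4


def bonferroni_threshold(level: Literal["groups", "categories"]) -> float:
    """Adjusted significance threshold: 0.05/9 for groups, 0.05/4 for categories."""
    if level == "groups":
        return 0.05 / N_GROUP_COMPARISONS
    if level == "categories":
        return 0.05 / N_CATEGORY_COMPARISONS
    raise ValueError(f"unknown level {level!r}")


def _corr_pairs() -> list[tuple[str, str]]:
    pairs = [("mean_ddi", "vdp_percent")]
    pairs += [("mean_ddi", p) for p in PFT_COLUMNS]
    pairs += [("vdp_percent", p) for p in PFT_COLUMNS]
    return pairs


def pairwise_correlations(
    table: pd.DataFrame,
    by: str = "group",
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-group Pearson r (two-sided p) for metric/PFT pairs.

    Missing PFT entries are dropped pairwise; a pair with fewer than 3
    complete observations is reported with r and p missing (NaN), not a
    number.
    """
    if pairs is None:
        pairs = _corr_pairs()
    rows = []
    for group, sub in table.groupby(by, sort=True):
        for x, y in pairs:
            if x not in sub.columns or y not in sub.columns:
                continue
            d = sub[[x, y]].dropna()
            n = len(d)
            if n < 3 or d[x].nunique() < 2 or d[y].nunique() < 2:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(d[x], d[y])
            rows.append(
                {by: group, "x": x, "y": y, "n": n, "r": r, "p": p}
            )
    return pd.DataFrame(rows)


def _pairwise_ranksum(a: np.ndarray, b: np.ndarray) -> float:
    return float(stats.ranksums(a, b).pvalue)


def _dunn_pvalues(samples: dict, pairs: Iterable[tuple]) -> dict:
    """Dunn's z-test p-values on pooled ranks, with tie correction."""
    labels = list(samples)
    pooled = np.concatenate([samples[g] for g in labels])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_rank = {}
    i = 0
    for g in labels:
        k = len(samples[g])
        mean_rank[g] = ranks[i : i + k].mean()
        i += k
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    out = {}
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / len(samples[a]) + 1.0 / len(samples[b])))
        z = (mean_rank[a] - mean_rank[b]) / se
        out[(a, b)] = float(2.0 * stats.norm.sf(abs(z)))
    return out


def group_tests(
    table: pd.DataFrame,
    level: Literal["groups", "categories"] = "groups",
    metrics: Sequence[str] = METRICS,
    pairwise_method: Literal["ranksum", "dunn"] = "ranksum",
) -> dict:
    """Kruskal-Wallis omnibus + pairwise comparisons per metric.

    Pairwise p-values are reported *unadjusted* and flagged significant
    against the Bonferroni-adjusted threshold for the level, matching the
    report-unadjusted / compare-to-adjusted-threshold convention.
    """
    by = "group" if level == "groups" else "category"
    threshold = bonferroni_threshold(level)
    results: dict = {"level": level, "threshold": threshold, "metrics": {}}
    for metric in metrics:
        samples = {
            g: sub[metric].dropna().to_numpy()
            for g, sub in table.groupby(by, sort=True)
        }
        samples = {g: v for g, v in samples.items() if len(v) >= 2}
        if len(samples) < 2:
            raise ValueError(f"need >= 2 groups with >= 2 observations for {metric}")
        vals = list(samples.values())
        if np.ptp(np.concatenate(vals)) == 0:  # all identical: H = 0 by definition
            h_stat, omnibus_p = 0.0, 1.0
        else:
            h_stat, omnibus_p = stats.kruskal(*vals)
        pair_list = list(combinations(sorted(samples), 2))
        if pairwise_method == "dunn":
            pvals = _dunn_pvalues(samples, pair_list)
        else:
            pvals = {
                (a, b): _pairwise_ranksum(samples[a], samples[b])
                for a, b in pair_list
            }
        pairwise = [
            {
                "a": a,
                "b": b,
                "p_unadjusted": pvals[(a, b)],
                "significant": bool(pvals[(a, b)] < threshold),
            }
            for a, b in pair_list
        ]
        results["metrics"][metric] = {
            "h_statistic": float(h_stat),
            "p_omnibus": float(omnibus_p),
            "pairwise": pairwise,
        }
    return results


def orientation_compare(
    table: pd.DataFrame,
    within: str,
    metrics: Sequence[str] = ("mean_ddi", "ddi_over_vdp"),
) -> dict:
    """Two-tailed t-test (axial vs coronal) for each metric within a group.

    A group missing one orientation yields missing (None) entries rather
    than an error.
    """
    sub = table[table["group"] == within]
    out: dict = {"group": within, "metrics": {}}
    for metric in metrics:
        ax = sub.loc[sub["orientation"] == "axial", metric].dropna().to_numpy()
        co = sub.loc[sub["orientation"] == "coronal", metric].dropna().to_numpy()
        if len(ax) < 2 or len(co) < 2:
            out["metrics"][metric] = {"t": None, "p": None, "n_axial": len(ax), "n_coronal": len(co)}
            continue
        if np.ptp(np.concatenate([ax, co])) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(ax, co)
        out["metrics"][metric] = {
            "t": float(t),
            "p": float(p),
            "n_axial": int(len(ax)),
            "n_coronal": int(len(co)),
        }
    return out


def load_cohort_table(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Required columns: subject_id, group, category, orientation, mean_ddi,
    vdp_percent.  Optional: ddi_over_vdp (derived when absent), fev1, fvc,
    fev1_fvc.  Raises with the offending row number on malformed numerics.
    """
    df = pd.read_csv(path)
    required = ["subject_id", "group", "category", "orientation", "mean_ddi", "vdp_percent"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    numeric = ["mean_ddi", "vdp_percent", "ddi_over_vdp", *PFT_COLUMNS]
    for col in numeric:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # header + 1-based
            raise ValueError(f"non-numeric value in column {col!r} at CSV row {row}")
        df[col] = coerced
    inf = df[[c for c in numeric if c in df.columns]].apply(np.isinf).any(axis=1)
    if inf.any():
        row = int(np.flatnonzero(inf)[0]) + 2
        raise ValueError(f"non-finite value at CSV row {row}")
    if "ddi_over_vdp" not in df.columns:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = df["mean_ddi"] / df["vdp_percent"]
        df["ddi_over_vdp"] = ratio.where(df["vdp_percent"] > 0)
    bad_orient = ~df["orientation"].isin(["axial", "coronal"])
    if bad_orient.any():
        row = int(np.flatnonzero(bad_orient)[0]) + 2
        raise ValueError(f"unknown orientation at CSV row {row}")
    return df
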