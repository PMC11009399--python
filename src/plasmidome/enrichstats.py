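"""Enrichment and comparative statistics for selected entity sets.

Pathway enrichment uses the upper-tail hypergeometric test with
Benjamini-Hochberg correction and a gene-ratio filter; 2x2 associations use
the odds ratio with Fisher's exact test; distribution comparisons use the
two-sample Kolmogorov-Smirnov test; lifestyle proportions use pairwise
chi-square with Wilson confidence intervals; length comparisons subtract
merged mobility-gene intervals before a Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "hypergeom_enrich",
    "odds_ratio_2x2",
    "ks_compare",
    "lifestyle_proportion_tests",
    "adjusted_length_compare",
    "merge_intervals",
]


def hypergeom_enrich(selected, background, annotations: dict,
                     min_gene_ratio: float = 0.1,
                     q_max: float = 0.01) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of terms in ``selected``.

    ``annotations`` maps entity id -> iterable of terms.  For each term with
    K carriers among the N background entities and k among the n selected,
    p = P(X >= k).  BH-FDR runs across terms; the returned table keeps terms
    with gene_ratio (k/n) > min_gene_ratio and q <= q_max.  Entities without
    annotations stay in N.
    """
    selected = set(selected)
    background = set(background)
    if not selected <= background:
        raise ValueError("selected entities must be a subset of the background")
    N, n = len(background), len(selected)
    term_bg: dict = {}
    term_sel: dict = {}
    for e in background:
        for t in set(annotations.get(e, ())):
            term_bg[t] = term_bg.get(t, 0) + 1
            if e in selected:
                term_sel[t] = term_sel.get(t, 0) + 1
    rows = []
    for t, K in sorted(term_bg.items()):
        k = term_sel.get(t, 0)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": t, "k": k, "n": n, "K": K, "N": N,
                     "gene_ratio": k / n if n else 0.0, "p": p})
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    table["odds_ratio"] = _table_or(table)
    return table[(table["gene_ratio"] > min_gene_ratio) & (table["q"] <= q_max)] \
        .reset_index(drop=True)


def _table_or(table: pd.DataFrame) -> pd.Series:
    a = table["k"].to_numpy(dtype=float)
    b = (table["n"] - table["k"]).to_numpy(dtype=float)
    c = (table["K"] - table["k"]).to_numpy(dtype=float)
    d = (table["N"] - table["K"] - table["n"] + table["k"]).to_numpy(dtype=float)
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    a, b, c, d = (np.where(zero, x + 0.5, x) for x in (a, b, c, d))
    return pd.Series(a * d / (b * c), index=table.index)


def odds_ratio_2x2(a: int, b: int, c: int, d: int):
    """(odds ratio, two-sided Fisher exact p) for the table [[a, b], [c, d]].

    Cells must be nonnegative integers; the Haldane-Anscombe +0.5 correction
    is applied to the odds ratio when any cell is zero.  An all-zero margin
    makes the odds ratio undefined (nan).
    """
    cells = (a, b, c, d)
    if any(x < 0 or int(x) != x for x in cells):
        raise ValueError("cells must be nonnegative integers")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        warnings.warn("a margin of the 2x2 table is zero; odds ratio undefined")
        _, p = stats.fisher_exact([[a, b], [c, d]])
        return np.nan, float(p)
    if 0 in cells:
        orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        orr = a * d / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(orr), float(p)


def ks_compare(counts_a, counts_b, method: str = "auto"):
    """Two-sample KS statistic D = sup |ECDF_a - ECDF_b| with its p-value."""
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if len(counts_a) == 0 or len(counts_b) == 0:
        raise ValueError("both samples must contain at least one observation")
    res = stats.ks_2samp(counts_a, counts_b, method=method)
    return float(res.statistic), float(res.pvalue)


def lifestyle_proportion_tests(presence: pd.DataFrame, annotations: pd.DataFrame,
                               metadata: pd.DataFrame):
    """Per-disease mobilizable fraction of present plasmid observations.

    The unit of observation is a (sample, present plasmid) cell.  Fractions
    get Wilson 95% CIs; group differences are pairwise chi-square tests on
    the mobilizable/non-mobilizable counts with BH correction.
    """
    lifestyles = annotations["lifestyle"]
    mob = presence.columns.isin(lifestyles.index[lifestyles == "mobilizable"])
    md = metadata.loc[presence.index]
    rows = []
    for d in sorted(md["disease"].unique()):
        block = presence.loc[(md["disease"] == d).to_numpy()]
        total = int(block.to_numpy().sum())
        if total == 0:
            warnings.warn(f"disease group {d!r} has no present plasmid observations")
            continue
        n_mob = int(block.loc[:, mob].to_numpy().sum())
        lo, hi = proportion_confint(n_mob, total, alpha=0.05, method="wilson")
        rows.append({"disease": d, "n_mobilizable": n_mob, "n_total": total,
                     "fraction": n_mob / total, "ci_lower": lo, "ci_upper": hi})
    table = pd.DataFrame(rows)
    tests = []
    for i in range(len(table)):
        for j in range(i + 1, len(table)):
            r1, r2 = table.iloc[i], table.iloc[j]
            cont = np.array([[r1["n_mobilizable"], r1["n_total"] - r1["n_mobilizable"]],
                             [r2["n_mobilizable"], r2["n_total"] - r2["n_mobilizable"]]])
            if cont.sum(axis=1).min() > 0 and cont.sum(axis=0).min() > 0:
                _, p, _, _ = stats.chi2_contingency(cont, correction=True)
                tests.append({"group_a": r1["disease"], "group_b": r2["disease"], "p": p})
    tests = pd.DataFrame(tests)
    if not tests.empty:
        tests["q"] = multipletests(tests["p"], method="fdr_bh")[1]
    return table, tests


def merge_intervals(intervals) -> list:
    """Union of 0-based half-open intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    merged = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _parse_intervals(spec: str) -> list:
    if not spec or (isinstance(spec, float) and np.isnan(spec)):
        return []
    return [tuple(map(int, part.split("-"))) for part in str(spec).split(";") if part]


def adjusted_length_compare(annotations: pd.DataFrame):
    """Wilcoxon comparison of lifestyle lengths net of mobility genes.

    Adjusted length = plasmid length minus the union length of its mobility
    gene intervals (overlaps merged before summation).  Returns the
    per-plasmid table and the two-sided rank-sum test between lifestyles.
    """
    adj = []
    for pid, row in annotations.iterrows():
        ivs = merge_intervals(_parse_intervals(row.get("mobility_intervals", "")))
        mob_len = sum(e - s for s, e in ivs)
        adj.append({"plasmid_id": pid, "lifestyle": row["lifestyle"],
                    "adjusted_length": int(row["length"]) - mob_len})
    table = pd.DataFrame(adj).set_index("plasmid_id")
    x = table.loc[table["lifestyle"] == "mobilizable", "adjusted_length"]
    y = table.loc[table["lifestyle"] == "non-mobilizable", "adjusted_length"]
    if len(x) and len(y):
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        test = {"mean_mobilizable": float(x.mean()), "mean_non_mobilizable": float(y.mean()),
                "p": float(res.pvalue)}
    else:
        test = {"mean_mobilizable": np.nan, "mean_non_mobilizable": np.nan, "p": np.nan}
    return table, test
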