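"""Plasmid deduplication, presence calling, depth filtering and richness.

The filtering chain mirrors a standard plasmidome workflow: near-identical
assemblies are collapsed onto the larger representative (identity strictly
above 95% over at least 95% of the larger plasmid), presence requires read
coverage over at least 70% of the plasmid length, and a cohort-wide depth
cutoff — 1% of the lowest present abundance in the shallowest sample —
masks abundances too low to trust given uneven sequencing depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import argrelextrema
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceMatrix

__all__ = [
    "dedup_plasmids",
    "call_presence",
    "apply_depth_cutoff",
    "richness_ratio",
    "length_trough",
]


@dataclass
class DedupResult:
    representatives: list
    cluster_map: dict  # member -> representative (representatives map to themselves)


def dedup_plasmids(lengths: dict, pairwise_matches,
                   min_identity: float = 0.95, min_coverage: float = 0.95) -> DedupResult:
    """Collapse near-duplicate plasmids onto the larger member.

    A pair qualifies when identity is strictly above ``min_identity`` and the
    aligned length covers at least ``min_coverage`` of the *larger* plasmid.
    Qualifying pairs are processed in decreasing order of the larger member's
    length (lexicographic id tie-break) and the smaller member is removed;
    chains therefore resolve deterministically and independently of input
    order.  Self-matches are ignored with a warning.
    """
    removed: set = set()
    cluster_map = {pid: pid for pid in lengths}
    candidates = []
    for a, b, identity, aligned_length in pairwise_matches:
        if a == b:
            warnings.warn(f"ignoring self-match for {a}")
            continue
        if not 0 <= identity <= 1:
            raise ValueError(f"identity out of [0, 1] for pair ({a}, {b}): {identity}")
        if lengths[a] != lengths[b]:
            big, small = (a, b) if lengths[a] > lengths[b] else (b, a)
        else:  # tie on length: the lexicographically smaller id represents
            big, small = (a, b) if a < b else (b, a)
        if identity > min_identity and aligned_length >= min_coverage * lengths[big]:
            candidates.append((lengths[big], big, small))
    # larger representatives absorb first; ties broken by id
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    for _, big, small in candidates:
        if big in removed or small in removed:
            continue
        removed.add(small)
        cluster_map[small] = big
    # path-compress members of removed representatives
    for pid in cluster_map:
        rep = cluster_map[pid]
        while cluster_map[rep] != rep:
            rep = cluster_map[rep]
        cluster_map[pid] = rep
    survivors = sorted(pid for pid in lengths if pid not in removed)
    return DedupResult(representatives=survivors, cluster_map=cluster_map)


def call_presence(abund: AbundanceMatrix, min_cov: float = 0.70) -> pd.DataFrame:
    """Present iff coverage_fraction >= min_cov (inclusive) and abundance > 0."""
    cov = abund.coverage
    if cov.isna().to_numpy().any():
        warnings.warn("missing coverage cells treated as 0")
        cov = cov.fillna(0.0)
    return cov.ge(min_cov) & abund.abundance.gt(0)


def apply_depth_cutoff(abund: AbundanceMatrix, presence: pd.DataFrame,
                       fraction: float = 0.01):
    """Mask presences below 1% of the shallowest sample's lowest abundance.

    The cutoff is ``fraction`` times the minimum abundance among plasmids
    called present in the sample with the lowest read depth.  Cells with
    abundance strictly below the cutoff are set absent; entities absent
    everywhere afterwards are dropped.  Returns (presence, cutoff).
    """
    shallow = abund.read_depth.idxmin()
    present_there = presence.loc[shallow]
    vals = abund.abundance.loc[shallow, present_there[present_there].index]
    vals = vals[vals > 0]
    if vals.empty:
        raise ValueError(
            f"shallowest sample {shallow!r} has no present plasmid; relax the "
            "presence filter (min_cov) before applying the depth cutoff")
    cutoff = fraction * float(vals.min())
    out = presence & abund.abundance.ge(cutoff)
    out = out.loc[:, out.any(axis=0)]
    return out, cutoff


def _pairwise_wilcoxon(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    labels = sorted(groups.unique())
    rows = []
    for i, g1 in enumerate(labels):
        for g2 in labels[i + 1:]:
            x = values[groups == g1].to_numpy()
            y = values[groups == g2].to_numpy()
            if len(x) == 0 or len(y) == 0:
                continue
            method = "exact" if max(len(x), len(y)) <= 20 else "asymptotic"
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
            rows.append({"group_a": g1, "group_b": g2, "statistic": res.statistic,
                         "p": res.pvalue})
    table = pd.DataFrame(rows)
    if not table.empty:
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    return table


def richness_ratio(presence: pd.DataFrame, taxa_profiles: pd.DataFrame,
                   metadata: pd.DataFrame):
    """Plasmid-to-species richness ratio per sample, with group comparisons.

    Richness is the count of present entities per sample.  Samples with zero
    species richness are excluded with a warning.  Group comparisons are
    pairwise two-sided Wilcoxon rank-sum tests on the ratio across disease
    groups with Benjamini-Hochberg correction.
    """
    plasmid_rich = presence.sum(axis=1)
    species_rich = taxa_profiles.gt(0).sum(axis=1)
    common = presence.index.intersection(taxa_profiles.index)
    table = pd.DataFrame({
        "plasmid_richness": plasmid_rich.loc[common],
        "species_richness": species_rich.loc[common],
    })
    zero = table["species_richness"] == 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} samples with zero species richness")
        table = table[~zero]
    table["ratio"] = table["plasmid_richness"] / table["species_richness"]
    table["disease"] = metadata.loc[table.index, "disease"]
    tests = _pairwise_wilcoxon(table["ratio"], table["disease"])
    return table, tests


def length_trough(lengths, n_grid: int = 512):
    """Position (bp) of the KDE trough between the two largest length modes.

    A Gaussian KDE is fitted on log10(length); the function returns the
    minimizing abscissa between the two highest local maxima, or None when
    the density is unimodal.
    """
    lengths = np.asarray(lengths, dtype=float)
    if len(lengths) < 10:
        raise ValueError(f"need at least 10 lengths, got {len(lengths)}")
    if np.any(lengths <= 0):
        raise ValueError("lengths must be positive")
    x = np.log10(lengths)
    kde = stats.gaussian_kde(x)
    grid = np.linspace(x.min() - 0.2, x.max() + 0.2, n_grid)
    dens = kde(grid)
    peaks = argrelextrema(dens, np.greater)[0]
    peaks = peaks[dens[peaks] > 0.05 * dens.max()]  # ignore tail ripples
    if len(peaks) < 2:
        return None
    top2 = sorted(sorted(peaks, key=lambda i: -dens[i])[:2])
    lo, hi = top2
    trough = lo + int(np.argmin(dens[lo:hi + 1]))
    if dens[trough] > 0.8 * min(dens[lo], dens[hi]):
        return None  # shoulder, not a genuine second mode
    return float(10 ** grid[trough])
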