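"""Sample-sample segment-sharing network and degree-preserving null model.

Two samples are connected when they share at least one plasmid segment
cluster; the edge weight is the number of shared clusters, i.e. the dot
product of the two samples' rows of the sample x segment incidence matrix.
Significance of group, edge and segment connectivity is assessed against an
ensemble of incidence matrices randomized by 2x2 checkerboard swaps, which
conserve every row and column sum (sample and segment degrees) exactly.
Empirical p-values use the add-one formula p = (1 + #{null >= obs}) / (1 + n)
so that no p-value is ever exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from numba import njit
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SharingNetwork",
    "NullEnsemble",
    "build_sharing_network",
    "permute_incidence",
    "group_connectivity_test",
    "edge_significance",
    "segment_significance",
    "strength_ratio",
    "cross_continental_summary",
]


@njit(cache=True)
def _swap_chain(M: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                n_attempts: int, seed: int) -> int:
    """In-place checkerboard swaps; returns the number of successful swaps.

    Each attempt draws two occupied cells (r1, c1), (r2, c2); if the
    opposite corners (r1, c2), (r2, c1) are empty the 2x2 checkerboard is
    flipped.  Sampling occupied cells directly keeps the acceptance rate
    high in sparse matrices.  An inline xorshift64* generator (two 32-bit
    lanes per draw) keeps the chain cheap for large ensembles.
    """
    k = len(rows)
    done = 0
    if k < 2:
        return 0
    s = np.uint64(seed) * np.uint64(0x9E3779B97F4A7C15) + np.uint64(1)
    for _ in range(n_attempts):
        s ^= s >> np.uint64(12)
        s ^= s << np.uint64(25)
        s ^= s >> np.uint64(27)
        v = s * np.uint64(0x2545F4914F6CDD1D)
        i = int(v & np.uint64(0xFFFFFFFF)) % k
        j = int(v >> np.uint64(32)) % k
        r1, c1 = rows[i], cols[i]
        r2, c2 = rows[j], cols[j]
        if r1 == r2 or c1 == c2:
            continue
        if M[r1, c2] == 0 and M[r2, c1] == 0:
            M[r1, c1] = 0
            M[r2, c2] = 0
            M[r1, c2] = 1
            M[r2, c1] = 1
            cols[i] = c2
            cols[j] = c1
            done += 1
    return done


def permute_incidence(incidence: pd.DataFrame, seed: int,
                      n_swaps: int | str = "auto"):
    """Degree-preserving randomization by repeated 2x2 checkerboard swaps.

    ``n_swaps`` is the number of swap *attempts*; "auto" uses 10x the number
    of 1-cells.  Row and column sums are conserved by construction.  If the
    matrix admits no checkerboard (e.g. all ones), the original is returned
    with ``flag`` set.  Returns (permuted DataFrame, info dict).
    """
    M = incidence.to_numpy(dtype=np.uint8).copy()
    ones = int(M.sum())
    if n_swaps == "auto":
        n_swaps = 10 * ones
    r, c = np.nonzero(M)
    done = _swap_chain(M, r.astype(np.int64), c.astype(np.int64),
                       int(n_swaps), int(seed) % (2 ** 32))
    info = {"n_attempts": int(n_swaps), "n_swapped": done, "flag_no_swap": done == 0}
    out = pd.DataFrame(M.astype(bool), index=incidence.index, columns=incidence.columns)
    return out, info


@dataclass
class NullEnsemble:
    """A fixed collection of degree-preserving randomizations of an incidence."""

    incidence: pd.DataFrame
    n_perm: int
    seed: int
    members: np.ndarray = field(init=False)      # (n_perm, n_samples, n_segments) uint8
    swap_counts: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        M0 = self.incidence.to_numpy(dtype=np.uint8)
        ones = int(M0.sum())
        n_swaps = 10 * ones
        child = np.random.SeedSequence(self.seed).generate_state(self.n_perm)
        self.members = np.empty((self.n_perm,) + M0.shape, dtype=np.uint8)
        self.swap_counts = np.empty(self.n_perm, dtype=np.int64)
        for t in range(self.n_perm):
            M = M0.copy()
            r, c = np.nonzero(M)
            self.swap_counts[t] = _swap_chain(M, r.astype(np.int64),
                                              c.astype(np.int64), n_swaps,
                                              int(child[t]))
            self.members[t] = M
        if ones and (self.swap_counts == 0).all():
            warnings.warn("no valid checkerboard swap exists; ensemble equals the original")


@dataclass
class SharingNetwork:
    weights: pd.DataFrame          # samples x samples, shared-cluster counts
    incidence: pd.DataFrame
    metadata: pd.DataFrame
    density: float

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for s in self.weights.index:
            g.add_node(s, **self.metadata.loc[s].to_dict())
        W = self.weights.to_numpy()
        ids = list(self.weights.index)
        iu, ju = np.triu_indices(len(ids), k=1)
        for i, j in zip(iu, ju):
            if W[i, j] > 0:
                g.add_edge(ids[i], ids[j], weight=int(W[i, j]))
        return g


def build_sharing_network(incidence: pd.DataFrame,
                          metadata: pd.DataFrame) -> SharingNetwork:
    """Weighted sample-sample graph: weight(u, v) = shared segment clusters."""
    missing = incidence.index.difference(metadata.index)
    if len(missing):
        raise ValueError(f"samples missing from metadata: {sorted(missing)}")
    M = incidence.to_numpy(dtype=np.int64)
    W = M @ M.T
    np.fill_diagonal(W, 0)
    n = len(incidence)
    n_pairs = n * (n - 1) // 2
    density = float((W > 0).sum() / 2) / n_pairs if n_pairs else 0.0
    weights = pd.DataFrame(W, index=incidence.index, columns=incidence.index)
    return SharingNetwork(weights=weights, incidence=incidence,
                          metadata=metadata.loc[incidence.index], density=density)


def _empirical_p(null: np.ndarray, observed: float) -> float:
    return (1 + int(np.sum(null >= observed))) / (1 + len(null))


def _group_masks(metadata: pd.DataFrame, samples: pd.Index,
                 exclude_from_geography=("obese",), include_geography=True):
    """Enumerate (label, row-mask pairs) for disease and disease x continent groups."""
    md = metadata.loc[samples]
    diseases = sorted(md["disease"].unique())
    continents = sorted(md["continent"].unique())
    groups = []
    for d in diseases:
        in_d = (md["disease"] == d).to_numpy()
        groups.append((f"{d}|all", in_d, None))
        if d in exclude_from_geography or not include_geography:
            continue
        for i, c1 in enumerate(continents):
            m1 = in_d & (md["continent"] == c1).to_numpy()
            groups.append((f"{d}|{c1}", m1, None))
            for c2 in continents[i + 1:]:
                m2 = in_d & (md["continent"] == c2).to_numpy()
                groups.append((f"{d}|{c1}~{c2}", m1, m2))
    return groups


def _group_stat(M: np.ndarray, mask1: np.ndarray, mask2) -> float:
    """Total within-group edge weight from column carrier counts.

    Same-group statistic sums C(k, 2) per segment; cross-group statistic
    sums k1 * k2, where k are carrier counts within each block.
    """
    if mask2 is None:
        k = M[mask1].sum(axis=0).astype(np.float64)
        return float((k * (k - 1)).sum() / 2)
    k1 = M[mask1].sum(axis=0).astype(np.float64)
    k2 = M[mask2].sum(axis=0).astype(np.float64)
    return float((k1 * k2).sum())


def group_connectivity_test(incidence: pd.DataFrame, metadata: pd.DataFrame,
                            ensemble: NullEnsemble,
                            exclude_from_geography=("obese",),
                            include_geography: bool = True) -> pd.DataFrame:
    """Within-disease and continental-block connectivity vs the null ensemble.

    The statistic per group is the total edge weight among qualifying sample
    pairs (both in the group; for cross-continent groups, one sample per
    continent).  Groups with fewer than 2 qualifying samples are skipped.
    """
    M0 = incidence.to_numpy(dtype=np.uint8)
    rows = []
    for label, m1, m2 in _group_masks(metadata, incidence.index, exclude_from_geography,
                                      include_geography):
        size = int(m1.sum()) + (int(m2.sum()) if m2 is not None else 0)
        if (m2 is None and m1.sum() < 2) or (m2 is not None and (m1.sum() < 1 or m2.sum() < 1)):
            continue
        obs = _group_stat(M0, m1, m2)
        null = np.array([_group_stat(ensemble.members[t], m1, m2)
                         for t in range(ensemble.n_perm)])
        rows.append({"group": label, "n_samples": size, "observed": obs,
                     "null_mean": float(null.mean()),
                     "p": _empirical_p(null, obs)})
    table = pd.DataFrame(rows)
    if not table.empty:
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    return table


def edge_significance(net: SharingNetwork, ensemble: NullEnsemble,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Per same-disease edge, empirical p of its weight vs the null ensemble.

    Benjamini-Hochberg correction is applied within each disease state; edges
    with q <= alpha are flagged significant.
    """
    md = net.metadata
    ids = list(net.weights.index)
    disease = md["disease"].to_numpy()
    continent = md["continent"].to_numpy()
    W0 = net.weights.to_numpy()
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    same = disease[iu] == disease[ju]
    iu, ju = iu[same], ju[same]
    obs = W0[iu, ju]
    keep = obs >= 1
    iu, ju, obs = iu[keep], ju[keep], obs[keep]
    count_ge = np.zeros(len(obs), dtype=np.int64)
    for t in range(ensemble.n_perm):
        M = ensemble.members[t].astype(np.int64)
        Wt = M @ M.T
        count_ge += Wt[iu, ju] >= obs
    p = (1 + count_ge) / (1 + ensemble.n_perm)
    table = pd.DataFrame({
        "sample_a": [ids[i] for i in iu],
        "sample_b": [ids[j] for j in ju],
        "disease": disease[iu],
        "cross_continental": continent[iu] != continent[ju],
        "weight": obs,
        "p": p,
    })
    table["q"] = np.nan
    for d in np.unique(table["disease"]):
        m = table["disease"] == d
        table.loc[m, "q"] = multipletests(table.loc[m, "p"], method="fdr_bh")[1]
    table["significant"] = table["q"] <= alpha
    return table


def segment_significance(incidence: pd.DataFrame, metadata: pd.DataFrame,
                         ensemble: NullEnsemble, alpha: float = 0.05) -> pd.DataFrame:
    """Per (segment, disease) within-group pair-count significance.

    The statistic is C(k, 2) with k the number of within-disease carriers;
    BH correction runs within each disease.  The selected fraction per
    disease is the share of segments with q <= alpha.
    """
    md = metadata.loc[incidence.index]
    M0 = incidence.to_numpy(dtype=np.int64)
    diseases = sorted(md["disease"].unique())
    rows = []
    for d in diseases:
        mask = (md["disease"] == d).to_numpy()
        k0 = M0[mask].sum(axis=0)
        obs = k0 * (k0 - 1) // 2
        count_ge = np.zeros(len(obs), dtype=np.int64)
        for t in range(ensemble.n_perm):
            kt = ensemble.members[t][mask].sum(axis=0).astype(np.int64)
            count_ge += (kt * (kt - 1) // 2) >= obs
        p = (1 + count_ge) / (1 + ensemble.n_perm)
        q = multipletests(p, method="fdr_bh")[1]
        for seg, o, pv, qv in zip(incidence.columns, obs, p, q):
            rows.append({"segment": seg, "disease": d, "observed_pairs": int(o),
                         "p": pv, "q": qv, "significant": qv <= alpha})
    return pd.DataFrame(rows)


def strength_ratio(net: SharingNetwork, mode: str = "per_capita") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within- vs between-disease strength ratio per sample, plus group tests.

    Strength is the sum of incident edge weights, split by whether the
    partner shares the node's disease state.  Mode "per_capita" divides each
    strength by the number of potential partners of that kind before taking
    the ratio; "raw" uses the plain sums.  Nodes with zero between-strength
    have an infinite ratio and are excluded from the rank tests (counted).
    """
    if mode not in ("per_capita", "raw"):
        raise ValueError(f"unknown mode {mode!r}")
    md = net.metadata
    disease = md["disease"].to_numpy()
    if len(np.unique(disease)) < 2:
        raise ValueError("strength ratios need at least two disease groups")
    W = net.weights.to_numpy(dtype=float)
    n = len(disease)
    same = disease[:, None] == disease[None, :]
    np.fill_diagonal(same, False)
    other = ~same
    np.fill_diagonal(other, False)
    within = (W * same).sum(axis=1)
    between = (W * other).sum(axis=1)
    n_within = same.sum(axis=1)
    n_between = other.sum(axis=1)
    if mode == "per_capita":
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(n_within > 0, within / np.maximum(n_within, 1), np.nan)
            b = np.where(n_between > 0, between / np.maximum(n_between, 1), np.nan)
    else:
        w, b = within.astype(float), between.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = w / b
    table = pd.DataFrame({"disease": disease, "within_strength": within,
                          "between_strength": between, "ratio": ratio},
                         index=net.weights.index)
    finite = table[np.isfinite(table["ratio"])]
    n_excluded = len(table) - len(finite)
    tests = []
    labels = sorted(finite["disease"].unique())
    for i, g1 in enumerate(labels):
        for g2 in labels[i + 1:]:
            x = finite.loc[finite["disease"] == g1, "ratio"]
            y = finite.loc[finite["disease"] == g2, "ratio"]
            if len(x) == 0 or len(y) == 0:
                continue
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            tests.append({"group_a": g1, "group_b": g2, "p": res.pvalue})
    tests = pd.DataFrame(tests)
    if not tests.empty:
        tests["q"] = multipletests(tests["p"], method="fdr_bh")[1]
    tests.attrs["n_excluded_infinite"] = n_excluded
    return table, tests


def cross_continental_summary(edge_table: pd.DataFrame) -> pd.DataFrame:
    """Per disease, fraction of cross-continental edges that are significant."""
    rows = []
    for d in sorted(edge_table["disease"].unique()):
        sub = edge_table[(edge_table["disease"] == d) & edge_table["cross_continental"]]
        frac = float(sub["significant"].mean()) if len(sub) else np.nan
        rows.append({"disease": d, "n_cross_continental_edges": len(sub),
                     "significant_fraction": frac})
    return pd.DataFrame(rows)
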