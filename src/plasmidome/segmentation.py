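"""Shared-segment extraction and clustering on circular plasmids.

Plasmid segments are stretches of at least 1 kb of DNA shared between two
distinct plasmids at >= 80% identity.  Because assembled plasmids are
circles linearized at an arbitrary origin, every sequence is doubled
(seq + seq) before alignment so that blocks straddling the origin are still
found in one piece; coordinates are then reduced modulo the plasmid length
and the duplicate hits introduced by doubling are collapsed.  Extracted
segment instances are clustered greedily (longest first) at 80% identity
with mutual coverage of at least 90% of both lengths, and a sample x
segment-cluster incidence matrix is derived from plasmid presence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from ._alignment import LocalHit, edit_identity, seed_extend_hits, smith_waterman, trim_hit

__all__ = [
    "SegmentHit",
    "SegmentCluster",
    "doubled_sequence",
    "find_shared_segments",
    "cluster_segments",
    "segment_incidence",
]


@dataclass
class SegmentHit:
    """A shared block between two plasmids, on original circular coordinates.

    ``start`` lies in [0, L); ``end = start + length`` may exceed L, which
    denotes a block wrapping across the linearization origin.
    """

    plasmid_a: str
    plasmid_b: str
    start_a: int
    end_a: int
    start_b: int
    end_b: int
    identity: float
    length: int


@dataclass
class SegmentCluster:
    cluster_id: str
    representative: str                      # representative sequence
    members: list = field(default_factory=list)   # (plasmid, start, end, identity)

    @property
    def member_plasmids(self) -> set:
        return {m[0] for m in self.members}


def doubled_sequence(seq: str) -> str:
    """Concatenate a circular sequence with itself (origin-spanning trick)."""
    return seq + seq


def _circular_overlap(s1: int, l1: int, s2: int, l2: int, L: int) -> int:
    """Overlap in bp of two (possibly wrapping) intervals on a circle of size L."""
    best = 0
    for shift in (-L, 0, L):
        a0, a1 = s1, s1 + l1
        b0, b1 = s2 + shift, s2 + shift + l2
        best = max(best, min(a1, b1) - max(a0, b0))
    return max(best, 0)


def _pair_hits(seq_a: str, seq_b: str, engine: str, double: bool) -> list[LocalHit]:
    if engine == "seed":
        da = doubled_sequence(seq_a) if double else seq_a
        db = doubled_sequence(seq_b) if double else seq_b
        raw = seed_extend_hits(da, db)
        trimmed = [trim_hit(h, da, db) for h in raw]
        return [h for h in trimmed if h is not None]
    if engine == "dp":
        # double only one side per run: a bridge between the two copies of a
        # block then has no second copy to land on in the other sequence
        runs = [(doubled_sequence(seq_a), seq_b), (seq_a, doubled_sequence(seq_b))] \
            if double else [(seq_a, seq_b)]
        out = []
        for da, db in runs:
            hit = smith_waterman(da, db)
            if hit is not None:
                hit = trim_hit(hit, da, db)
            if hit is not None:
                out.append(hit)
        return out
    raise ValueError(f"unknown alignment engine {engine!r}; use 'seed' or 'dp'")


def find_shared_segments(plasmids: dict, min_len: int = 1000, min_id: float = 0.80,
                         presence: pd.DataFrame | None = None,
                         engine: str = "seed", double: bool = True) -> list[SegmentHit]:
    """All-vs-all shared blocks of length >= min_len at identity >= min_id.

    Alignment runs on doubled sequences; duplicate hits at +L offsets are
    collapsed after reducing coordinates modulo the plasmid length, and
    overlapping hits on the same plasmid pair (> 50% reciprocal overlap) are
    merged keeping the higher-identity one.  If a presence matrix is given,
    only hits whose two plasmids together occur in at least two samples are
    retained.
    """
    ids = sorted(plasmids)
    hits: list[SegmentHit] = []
    for pa, pb in combinations(ids, 2):
        La, Lb = len(plasmids[pa]), len(plasmids[pb])
        raw = _pair_hits(plasmids[pa], plasmids[pb], engine, double)
        cand = []
        for h in raw:
            length = h.end_a - h.start_a
            cap = min(La, Lb)
            sa, sb = h.start_a, h.start_b
            identity = h.identity
            if length > cap:
                # doubling can tile a full-plasmid match twice; trim to one turn
                length = cap
                identity, _ = edit_identity(
                    doubled_sequence(plasmids[pa])[sa:sa + length],
                    doubled_sequence(plasmids[pb])[sb:sb + length])
            if length < min_len or identity < min_id:
                continue
            cand.append(SegmentHit(pa, pb, sa % La, sa % La + length,
                                   sb % Lb, sb % Lb + length, identity, length))
        # collapse +L duplicates and >50% reciprocal overlaps; longest first,
        # so a maximal block beats its own higher-identity sub-intervals
        cand.sort(key=lambda h: (-h.length, -round(h.identity, 4), h.start_a))
        kept: list[SegmentHit] = []
        for h in cand:
            dup = False
            for g in kept:
                ov_a = _circular_overlap(h.start_a, h.length, g.start_a, g.length, La)
                ov_b = _circular_overlap(h.start_b, h.length, g.start_b, g.length, Lb)
                if ov_a > 0.5 * min(h.length, g.length) and \
                   ov_b > 0.5 * min(h.length, g.length):
                    dup = True
                    break
            if not dup:
                kept.append(h)
        hits.extend(kept)
    if presence is not None:
        filtered = []
        for h in hits:
            cols = [c for c in (h.plasmid_a, h.plasmid_b) if c in presence.columns]
            carriers = presence[cols].any(axis=1).sum() if cols else 0
            if carriers >= 2:
                filtered.append(h)
        hits = filtered
    return hits


def _extract(plasmids: dict, pid: str, start: int, length: int) -> str:
    return doubled_sequence(plasmids[pid])[start:start + length]


def cluster_segments(hits: list[SegmentHit], plasmids: dict,
                     min_id: float = 0.80, mutual_cov: float = 0.90) -> list[SegmentCluster]:
    """Greedy longest-first clustering of extracted segment instances.

    Each hit contributes its two aligned stretches as segment instances;
    near-duplicate instances on the same plasmid (> 50% reciprocal overlap)
    are collapsed onto the longer one.  Instances are then sorted by
    decreasing length and each joins the first cluster whose representative
    aligns at >= min_id identity with the alignment covering >= mutual_cov
    of BOTH lengths (enforced as a length-ratio precondition plus a global
    alignment identity check), else founds a new cluster.
    """
    instances: dict[str, list] = {}
    for h in hits:
        for pid, s in ((h.plasmid_a, h.start_a), (h.plasmid_b, h.start_b)):
            L = len(plasmids[pid])
            rows = instances.setdefault(pid, [])
            merged = False
            for r in rows:
                ov = _circular_overlap(s, h.length, r[0], r[1], L)
                if ov > 0.5 * min(h.length, r[1]):
                    if h.length > r[1]:
                        r[0], r[1] = s, h.length
                    merged = True
                    break
            if not merged:
                rows.append([s, h.length])
    flat = [(pid, s, ln) for pid, rows in instances.items() for s, ln in rows]
    flat.sort(key=lambda t: (-t[2], t[0], t[1]))
    clusters: list[SegmentCluster] = []
    for pid, s, ln in flat:
        seq = _extract(plasmids, pid, s, ln)
        placed = False
        for cl in clusters:
            rep = cl.representative
            if min(len(rep), ln) < mutual_cov * max(len(rep), ln):
                continue
            identity, _ = edit_identity(rep, seq)
            if identity >= min_id:
                cl.members.append((pid, s, s + ln, identity))
                placed = True
                break
        if not placed:
            cl = SegmentCluster(cluster_id=f"C{len(clusters):04d}", representative=seq)
            cl.members.append((pid, s, s + ln, 1.0))
            clusters.append(cl)
    return clusters


def segment_incidence(clusters: list[SegmentCluster],
                      presence: pd.DataFrame) -> pd.DataFrame:
    """Sample x segment-cluster incidence via presence of carrying plasmids.

    A sample carries a cluster iff it carries at least one member plasmid;
    clusters carried by fewer than two samples are dropped.
    """
    orphans = sorted({p for cl in clusters for p in cl.member_plasmids}
                     - set(presence.columns))
    if orphans:
        raise ValueError(f"member plasmids missing from presence matrix: {orphans}")
    cols = {}
    for cl in clusters:
        carried = presence[sorted(cl.member_plasmids)].any(axis=1)
        if carried.sum() >= 2:
            cols[cl.cluster_id] = carried
    if not cols:
        return pd.DataFrame(index=presence.index)
    return pd.DataFrame(cols, index=presence.index)
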