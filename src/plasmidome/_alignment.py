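"""Pairwise local alignment primitives for segment detection.

Two engines are provided: a seed-and-extend engine (exact k-mer seeds,
diagonal chaining, ungapped X-drop extension, identity scored by a global
edit alignment of the extended region) used for production runs, and a full
dynamic-programming Smith-Waterman (linear gap penalty, vectorized by row)
used as a reference on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

__all__ = ["LocalHit", "smith_waterman", "seed_extend_hits", "edit_identity",
           "trim_hit"]

_ENC = np.zeros(128, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _ENC[ord(_c)] = _i


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    bad = ~np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    if bad.any():
        pos = int(np.flatnonzero(bad)[0])
        raise ValueError(f"non-ACGT character {chr(arr[pos])!r} at position {pos}")
    return _ENC[arr]


@dataclass
class LocalHit:
    """A local alignment between two sequences (0-based half-open)."""

    start_a: int
    end_a: int
    start_b: int
    end_b: int
    identity: float   # matches / alignment columns
    columns: int
    score: float = 0.0

    @property
    def length(self) -> int:
        return self.end_a - self.start_a


def edit_identity(a: str, b: str) -> tuple[float, int]:
    """(matches/columns, columns) of the global edit alignment of a and b."""
    res = edlib.align(a, b, mode="NW", task="path")
    matches = cols = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            cols += n
            if ch == "=":
                matches += n
    return matches / cols, cols


def _cigar_ops(cigar: str) -> list[tuple[str, int]]:
    ops, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    return ops


def trim_hit(hit: LocalHit, a: str, b: str, anchor: int = 4) -> LocalHit | None:
    """Trim alignment ends back to a run of ``anchor`` consecutive matches.

    Local extension can drag a few spurious flanking matches into a hit;
    trimming both ends to the first/last solid match run makes reported hit
    boundaries (and therefore the length threshold) reflect the homologous
    block itself.  Identity and column count are recomputed on the retained
    span.  Returns None if no anchored span remains.
    """
    sub_a = a[hit.start_a:hit.end_a]
    sub_b = b[hit.start_b:hit.end_b]
    res = edlib.align(sub_a, sub_b, mode="NW", task="path")
    cols = []
    for op, n in _cigar_ops(res["cigar"]):
        cols.extend([op] * n)
    run = 0
    lo = None
    for i, op in enumerate(cols):
        run = run + 1 if op == "=" else 0
        if run == anchor:
            lo = i - anchor + 1
            break
    if lo is None:
        return None
    run = 0
    for j in range(len(cols) - 1, -1, -1):
        run = run + 1 if cols[j] == "=" else 0
        if run == anchor:
            hi = j + anchor  # exclusive
            break
    da_l = sum(1 for op in cols[:lo] if op in "=XI")
    db_l = sum(1 for op in cols[:lo] if op in "=XD")
    da_r = sum(1 for op in cols[hi:] if op in "=XI")
    db_r = sum(1 for op in cols[hi:] if op in "=XD")
    kept = cols[lo:hi]
    matches = sum(1 for op in kept if op == "=")
    return LocalHit(start_a=hit.start_a + da_l, end_a=hit.end_a - da_r,
                    start_b=hit.start_b + db_l, end_b=hit.end_b - db_r,
                    identity=matches / len(kept), columns=len(kept),
                    score=hit.score)


def smith_waterman(a: str, b: str, match: int = 1, mismatch: int = -3,
                   gap: int = -4) -> LocalHit | None:
    """Best local alignment by full DP with a linear gap penalty.

    Rows are vectorized; the in-row gap recurrence is closed into a running
    maximum, which is exact for linear gaps.  Default scores penalize
    mismatches steeply (megablast-like) so unrelated flanks — including the
    inter-copy junk created by circular doubling — cannot bridge two
    homologous blocks; blocks at >= 80% identity still score positively.
    Returns None when no positive-scoring alignment exists.
    """
    ea, eb = _encode(a), _encode(b)
    n, m = len(ea), len(eb)
    gp = -gap
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    jj = np.arange(1, m + 1, dtype=np.int32)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        s = np.where(eb == ea[i - 1], match, mismatch).astype(np.int32)
        diag = H[i - 1, :-1] + s
        up = H[i - 1, 1:] + gap
        M = np.maximum(0, np.maximum(diag, up))
        run = np.maximum.accumulate(M + gp * jj)
        H[i, 1:] = np.maximum(M, run - gp * jj)
        j = int(np.argmax(H[i]))
        if H[i, j] > best:
            best, bi, bj = int(H[i, j]), i, j
    if best <= 0:
        return None
    # traceback by neighbor inspection
    i, j = bi, bj
    matches = cols = 0
    while H[i, j] > 0:
        s = match if ea[i - 1] == eb[j - 1] else mismatch
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + s:
            matches += int(s == match)
            cols += 1
            i, j = i - 1, j - 1
        elif j > 0 and H[i, j] == H[i, j - 1] + gap:
            cols += 1
            j -= 1
        elif i > 0 and H[i, j] == H[i - 1, j] + gap:
            cols += 1
            i -= 1
        else:  # pragma: no cover - unreachable for consistent scores
            break
    return LocalHit(start_a=i, end_a=bi, start_b=j, end_b=bj,
                    identity=matches / cols if cols else 0.0,
                    columns=cols, score=best)


def _xdrop_right(ea: np.ndarray, eb: np.ndarray, pa: int, pb: int,
                 xdrop: int) -> int:
    score = best = 0
    best_off = 0
    off = 0
    while pa + off < len(ea) and pb + off < len(eb):
        score += 1 if ea[pa + off] == eb[pb + off] else -1
        off += 1
        if score > best:
            best, best_off = score, off
        elif best - score > xdrop:
            break
    return best_off


def _xdrop_left(ea: np.ndarray, eb: np.ndarray, pa: int, pb: int,
                xdrop: int) -> int:
    score = best = 0
    best_off = 0
    off = 0
    while pa - off - 1 >= 0 and pb - off - 1 >= 0:
        score += 1 if ea[pa - off - 1] == eb[pb - off - 1] else -1
        off += 1
        if score > best:
            best, best_off = score, off
        elif best - score > xdrop:
            break
    return best_off


def seed_extend_hits(a: str, b: str, k: int = 16, max_gap: int = 400,
                     band: int = 32, xdrop: int = 20,
                     max_kmer_occ: int = 16) -> list[LocalHit]:
    """Candidate local alignments between a and b via exact k-mer seeding.

    Shared k-mers are chained along diagonals (tolerance ``band`` columns,
    at most ``max_gap`` bp between consecutive seeds), chains are extended
    ungapped with an X-drop, and the extended region is rescored with a
    global edit alignment to obtain identity over alignment columns.
    """
    ea, eb = _encode(a), _encode(b)
    if len(a) < k or len(b) < k:
        return []
    index: dict = {}
    for j in range(len(b) - k + 1):
        index.setdefault(b[j:j + k], []).append(j)
    seeds = []
    for i in range(len(a) - k + 1):
        pos = index.get(a[i:i + k])
        if pos and len(pos) <= max_kmer_occ:
            for j in pos:
                seeds.append((i - j, i))
    if not seeds:
        return []
    seeds.sort()
    # chain seeds into clusters along (nearly) constant diagonals
    clusters = []
    cur_diag, cur = seeds[0][0], [seeds[0]]
    for d, i in seeds[1:]:
        if d == cur_diag and i - cur[-1][1] <= max_gap:
            cur.append((d, i))
        else:
            clusters.append(cur)
            cur_diag, cur = d, [(d, i)]
    clusters.append(cur)
    # merge clusters on nearby diagonals with overlapping/nearby query spans
    clusters.sort(key=lambda c: (c[0][0], c[0][1]))
    merged = []
    for c in clusters:
        if merged:
            p = merged[-1]
            if abs(c[0][0] - p[-1][0]) <= band and \
               c[0][1] <= max(i for _, i in p) + max_gap:
                merged[-1] = p + c
                continue
        merged.append(c)
    hits = []
    for c in merged:
        diag = int(round(float(np.median([d for d, _ in c]))))
        ia0 = min(i for _, i in c)
        ia1 = max(i for _, i in c) + k
        ib0, ib1 = ia0 - diag, ia1 - diag
        if ib0 < 0:
            ia0 -= ib0
            ib0 = 0
        if ib1 > len(eb):
            ia1 -= ib1 - len(eb)
            ib1 = len(eb)
        if ia1 <= ia0:
            continue
        left = min(_xdrop_left(ea, eb, ia0, ib0, xdrop), ia0, ib0)
        right = _xdrop_right(ea, eb, ia1, ib1, xdrop)
        sa, ea_ = ia0 - left, ia1 + right
        sb, eb_ = ib0 - left, ib1 + right
        identity, cols = edit_identity(a[sa:ea_], b[sb:eb_])
        hits.append(LocalHit(start_a=sa, end_a=ea_, start_b=sb, end_b=eb_,
                             identity=identity, columns=cols))
    return hits
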