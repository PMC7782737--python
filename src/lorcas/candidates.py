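"""Candidate-read detection: sampled k-mer index, DDF seed scoring, chaining.

For a template read, every shared k-mer with another read yields a
(template offset, candidate offset, strand) pair.  The distance-difference
factor (DDF) score of a pair counts the other same-strand pairs whose
offset difference agrees within a tolerance; the top-scoring pair is the
seed.  The seed's supporting pairs are then reduced to the longest strictly
co-linear chain (a longest-increasing-subsequence computation), which kills
off-diagonal false positives.  The chain size is the hit's score and its
first/last anchors give the approximate mapped intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from . import _align
from .io_core import PafRecord, RawRead


@dataclass(frozen=True)
class KmerPair:
    """Matching k-mers: template offset, candidate forward-strand offset."""

    tpos: int
    cpos: int
    strand: str


@dataclass
class Chain:
    """Strictly co-linear k-mer pairs (increasing in both coordinates)."""

    pairs: list[KmerPair]
    k: int

    @property
    def size(self) -> int:
        return len(self.pairs)

    @property
    def span_t(self) -> tuple[int, int]:
        return self.pairs[0].tpos, self.pairs[-1].tpos + self.k

    def __post_init__(self):
        for a, b in zip(self.pairs, self.pairs[1:]):
            if b.tpos <= a.tpos or a.strand != b.strand:
                raise ValueError("chain not co-linear")
            ok = b.cpos > a.cpos if a.strand == "+" else b.cpos < a.cpos
            if not ok:
                raise ValueError("chain not co-linear")


@dataclass
class CandidateHit:
    template_id: str
    candidate_id: str
    strand: str
    seed: KmerPair
    ddf_score: int
    approx_t_interval: tuple[int, int]
    approx_c_interval: tuple[int, int]  # on the candidate's forward strand
    # chain anchors in template / candidate-oriented coordinates
    chain_t: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    chain_c: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))


# ---------------------------------------------------------------------------
# k-mer machinery
# ---------------------------------------------------------------------------


def kmer_codes(codes: np.ndarray, k: int):
    """Forward and reverse-complement 2-bit k-mer codes at every offset."""
    n = len(codes)
    if n < k:
        empty = np.empty(0, np.int64)
        return empty, empty
    m = n - k + 1
    fwd = np.zeros(m, np.int64)
    rev = np.zeros(m, np.int64)
    for j in range(k):
        fwd = (fwd << 2) | codes[j : j + m]
        rev |= (3 - codes[j : j + m]).astype(np.int64) << (2 * j)
    return fwd, rev


class KmerIndex:
    """Canonical sampled k-mer -> (read index, offset, strand) postings."""

    def __init__(self, reads: Sequence[RawRead], k: int = 13, stride: int = 5,
                 max_occ: int = 500):
        if not 8 <= k <= 21:
            raise ValueError("k must be in [8, 21]")
        self.k = k
        self.stride = stride
        self.max_occ = max_occ
        self.reads = list(reads)
        self.ids = [r.id for r in self.reads]
        self.lengths = np.array([r.length for r in self.reads], np.int64)
        self.codes = [_align.encode(r.sequence) for r in self.reads]

        keys, rids, offs, strands = [], [], [], []
        for ridx, c in enumerate(self.codes):
            fwd, rev = kmer_codes(c, k)
            if len(fwd) == 0:
                continue
            sel = np.arange(0, len(fwd), stride)
            f, r = fwd[sel], rev[sel]
            canon = np.minimum(f, r)
            keys.append(canon)
            rids.append(np.full(len(sel), ridx, np.int32))
            offs.append(sel.astype(np.int32))
            strands.append((f <= r).astype(np.uint8))  # 1 = canonical == fwd
        if not keys:
            self._keys = np.empty(0, np.int64)
            self._order = np.empty(0, np.int64)
            self._bounds = {}
            return
        keys = np.concatenate(keys)
        self._rids = np.concatenate(rids)
        self._offs = np.concatenate(offs)
        self._strands = np.concatenate(strands)
        order = np.argsort(keys, kind="stable")
        self._keys = keys[order]
        self._order = order
        uniq, starts, counts = np.unique(
            self._keys, return_index=True, return_counts=True
        )
        self._bounds = {
            int(u): (int(s), int(s + c))
            for u, s, c in zip(uniq, starts, counts)
            if c <= max_occ  # repeat k-mers are masked
        }

    def lookup(self, canon: int):
        """Postings (read indices, offsets, strand flags) for a canonical key."""
        b = self._bounds.get(int(canon))
        if b is None:
            empty = np.empty(0, np.int32)
            return empty, empty, np.empty(0, np.uint8)
        sel = self._order[b[0] : b[1]]
        return self._rids[sel], self._offs[sel], self._strands[sel]

    def batch_lookup(self, keys: np.ndarray):
        """Vectorized posting expansion for an array of canonical keys.

        Returns (query_row, read_idx, offset, strand) parallel arrays where
        query_row indexes into ``keys``.
        """
        if len(self._keys) == 0 or len(keys) == 0:
            e = np.empty(0, np.int64)
            return e, e.astype(np.int32), e.astype(np.int32), e.astype(np.uint8)
        lo = np.searchsorted(self._keys, keys, side="left")
        hi = np.searchsorted(self._keys, keys, side="right")
        counts = hi - lo
        counts[counts > self.max_occ] = 0  # masked repeat k-mers
        total = int(counts.sum())
        if total == 0:
            e = np.empty(0, np.int64)
            return e, e.astype(np.int32), e.astype(np.int32), e.astype(np.uint8)
        rows = np.repeat(np.arange(len(keys)), counts)
        cum = np.cumsum(counts) - counts
        within = np.arange(total) - np.repeat(cum, counts)
        sel = self._order[np.repeat(lo, counts) + within]
        return rows, self._rids[sel], self._offs[sel], self._strands[sel]

    def read_index(self, read_id: str) -> int:
        return self.ids.index(read_id)


def index_kmers(reads: Sequence[RawRead], k: int = 13, sample_stride: int = 5,
                max_occ: int = 500) -> KmerIndex:
    return KmerIndex(reads, k=k, stride=sample_stride, max_occ=max_occ)


def query_profile(codes: np.ndarray, k: int, stride: int = 1):
    """(positions, canonical codes, strand flags) for the query side."""
    fa, ra = kmer_codes(codes, k)
    sel = np.arange(0, len(fa), stride)
    return sel, np.minimum(fa, ra)[sel], (fa <= ra)[sel]


def target_profile(codes: np.ndarray, k: int):
    """Sorted canonical k-mer profile for the target side (cacheable)."""
    fb, rb = kmer_codes(codes, k)
    cb = np.minimum(fb, rb)
    sb = fb <= rb
    order_b = np.argsort(cb, kind="stable")
    return cb[order_b], order_b, sb


def match_kmer_pairs(a: np.ndarray, b: np.ndarray, k: int, stride: int = 1,
                     max_occ: int = 50, a_profile=None, b_profile=None):
    """All matching k-mer pairs between two code arrays.

    Returns (tpos, bpos, strand) arrays with bpos on b's forward strand.
    Precomputed ``a_profile``/``b_profile`` (from query_profile /
    target_profile) avoid re-hashing when one side is reused across calls.
    """
    if len(a) < k or len(b) < k:
        e = np.empty(0, np.int64)
        return e, e, np.empty(0, "U1")
    sel_a, ca, sa = a_profile if a_profile is not None else query_profile(a, k, stride)
    cb_sorted, order_b, sb = b_profile if b_profile is not None else target_profile(b, k)
    if len(ca) == 0 or len(cb_sorted) == 0:
        e = np.empty(0, np.int64)
        return e, e, np.empty(0, "U1")
    lo = np.searchsorted(cb_sorted, ca, side="left")
    hi = np.searchsorted(cb_sorted, ca, side="right")
    counts = hi - lo
    counts[counts > max_occ] = 0  # drop over-represented keys on the b side
    total = int(counts.sum())
    if total == 0:
        e = np.empty(0, np.int64)
        return e, e, np.empty(0, "U1")
    rows = np.repeat(np.arange(len(ca)), counts)
    cum = np.cumsum(counts) - counts
    within = np.arange(total) - np.repeat(cum, counts)
    js = order_b[np.repeat(lo, counts) + within]
    strand = np.where(sa[rows] == sb[js], "+", "-").astype("U1")
    return sel_a[rows].astype(np.int64), js.astype(np.int64), strand


# ---------------------------------------------------------------------------
# DDF scoring and chaining
# ---------------------------------------------------------------------------


@njit(cache=True)
def _lis_kernel(c):  # pragma: no cover - exercised via wrapper
    n = c.shape[0]
    tails = np.empty(n, c.dtype)  # smallest chain-end cpos per length
    tails_idx = np.empty(n, np.int64)
    parent = np.full(n, -1, np.int64)
    m = 0
    for i in range(n):
        lo, hi = 0, m
        while lo < hi:  # first tails[j] >= c[i]
            mid = (lo + hi) // 2
            if tails[mid] < c[i]:
                lo = mid + 1
            else:
                hi = mid
        tails[lo] = c[i]
        tails_idx[lo] = i
        parent[i] = tails_idx[lo - 1] if lo > 0 else -1
        if lo == m:
            m += 1
    out = np.empty(m, np.int64)
    i = tails_idx[m - 1]
    p = m
    while i != -1:
        p -= 1
        out[p] = i
        i = parent[i]
    return out


def longest_colinear_chain(tpos: np.ndarray, cpos: np.ndarray) -> np.ndarray:
    """Indices of the longest chain strictly increasing in both coordinates.

    O(n log n) patience sorting; pairs sorted by (tpos asc, cpos desc) so a
    strictly-increasing subsequence in cpos is strictly increasing in tpos.
    """
    n = len(tpos)
    if n == 0:
        return np.empty(0, np.int64)
    order = np.lexsort((-cpos, tpos))
    chain = _lis_kernel(cpos[order].astype(np.int64))
    return order[chain]


def ddf_scores(diffs: np.ndarray, epsilon: int) -> np.ndarray:
    """Per-pair count of same-strand pairs within |d_i - d_j| <= epsilon."""
    order = np.argsort(diffs)
    s = diffs[order]
    hi = np.searchsorted(s, diffs + epsilon, side="right")
    lo = np.searchsorted(s, diffs - epsilon, side="left")
    return (hi - lo).astype(np.int64)


def ddf_seed_and_chain(
    template: RawRead,
    candidate: RawRead,
    pairs: Sequence[KmerPair],
    epsilon: int = 32,
    k: int = 13,
    min_chain: int = 3,
) -> Optional[CandidateHit]:
    """Score pairs with the DDF, chain the seed's supporters, build a hit.

    ``pairs`` must all share one strand; candidate offsets are forward-strand.
    Returns None when no chain of at least ``min_chain`` anchors exists.
    """
    if not pairs:
        return None
    strand = pairs[0].strand
    if any(p.strand != strand for p in pairs):
        raise ValueError("mixed-strand pairs")
    tpos = np.array([p.tpos for p in pairs], np.int64)
    cfwd = np.array([p.cpos for p in pairs], np.int64)
    clen = candidate.length
    cori = clen - k - cfwd if strand == "-" else cfwd
    hit = _build_hit(
        template.id, candidate.id, template.length, clen, tpos, cori, strand,
        epsilon, k, min_chain,
    )
    return hit


def _build_hit(template_id, candidate_id, tlen, clen, tpos, cori, strand,
               epsilon, k, min_chain) -> Optional[CandidateHit]:
    # dedupe identical pairs
    key = tpos * (clen + 1) + cori
    _, uidx = np.unique(key, return_index=True)
    tpos, cori = tpos[uidx], cori[uidx]
    diffs = tpos - cori
    scores = ddf_scores(diffs, epsilon)
    best = np.flatnonzero(scores == scores.max())
    # deterministic seed tie-break: smallest (tpos, cpos)
    seed_i = best[np.lexsort((cori[best], tpos[best]))[0]]
    support = np.abs(diffs - diffs[seed_i]) <= epsilon
    st, sc = tpos[support], cori[support]
    chain_idx = longest_colinear_chain(st, sc)
    if len(chain_idx) < min_chain:
        return None
    ct, cc = st[chain_idx], sc[chain_idx]
    t_iv = (int(ct[0]), int(ct[-1]) + k)
    c_iv_ori = (int(cc[0]), int(cc[-1]) + k)
    if strand == "-":
        c_iv = (clen - c_iv_ori[1], clen - c_iv_ori[0])
        seed_cfwd = clen - k - int(cori[seed_i])
    else:
        c_iv = c_iv_ori
        seed_cfwd = int(cori[seed_i])
    return CandidateHit(
        template_id=template_id,
        candidate_id=candidate_id,
        strand=strand,
        seed=KmerPair(int(tpos[seed_i]), seed_cfwd, strand),
        ddf_score=int(len(chain_idx)),
        approx_t_interval=t_iv,
        approx_c_interval=c_iv,
        chain_t=ct,
        chain_c=cc,
    )


def find_candidates(
    template: RawRead,
    index: KmerIndex,
    epsilon: int = 32,
    min_chain: int = 3,
    exclude_self: bool = True,
    query_stride: int = 1,
) -> list[CandidateHit]:
    """All candidate hits of ``template`` against an indexed read set.

    The template is scanned at ``query_stride`` (default every position;
    only the index side is sampled), which preserves sensitivity on
    high-error templates.
    """
    k = index.k
    tcodes = _align.encode(template.sequence)
    fwd, rev = kmer_codes(tcodes, k)
    if len(fwd) == 0:
        return []
    sel = np.arange(0, len(fwd), query_stride)
    canon = np.minimum(fwd, rev)[sel]
    tstrand = (fwd <= rev)[sel]
    try:
        self_idx = index.read_index(template.id) if exclude_self else -1
    except ValueError:
        self_idx = -1

    rows, rids, offs, strands = index.batch_lookup(canon)
    if len(rows) == 0:
        return []
    keep = rids != self_idx
    rows, rids, offs, strands = rows[keep], rids[keep], offs[keep], strands[keep]
    if len(rows) == 0:
        return []
    tpos = sel[rows].astype(np.int64)
    cfwd = offs.astype(np.int64)
    # pair strand: '+' when both k-mers canonicalize on the same strand
    same = strands == tstrand[rows].astype(np.uint8)

    hits: list[CandidateHit] = []
    group_key = rids.astype(np.int64) * 2 + same
    order = np.argsort(group_key, kind="stable")
    group_key = group_key[order]
    starts = np.flatnonzero(np.diff(group_key, prepend=group_key[0] - 1))
    bounds = list(starts) + [len(group_key)]
    for gi in range(len(starts)):
        lo, hi = bounds[gi], bounds[gi + 1]
        sel_g = order[lo:hi]
        ridx = int(rids[sel_g[0]])
        strand = "+" if same[sel_g[0]] else "-"
        clen = int(index.lengths[ridx])
        tp = tpos[sel_g]
        cf = cfwd[sel_g]
        cori = clen - k - cf if strand == "-" else cf
        hit = _build_hit(
            template.id, index.ids[ridx], template.length, clen,
            tp, cori, strand, epsilon, k, min_chain,
        )
        if hit is not None:
            hits.append(hit)
    return hits


def top_candidates(hits: list[CandidateHit], m: int) -> list[CandidateHit]:
    """Best ``m`` hits: score desc, template span desc, candidate id asc."""
    if m < 1:
        raise ValueError("m must be >= 1")
    def sort_key(h: CandidateHit):
        span = h.approx_t_interval[1] - h.approx_t_interval[0]
        return (-h.ddf_score, -span, h.candidate_id)
    return sorted(hits, key=sort_key)[:m]


def hits_to_paf(hits: list[CandidateHit], lengths: dict[str, int]) -> list[PafRecord]:
    records = []
    for h in hits:
        records.append(
            PafRecord(
                q_name=h.candidate_id,
                q_len=lengths[h.candidate_id],
                q_start=h.approx_c_interval[0],
                q_end=h.approx_c_interval[1],
                strand=h.strand,
                t_name=h.template_id,
                t_len=lengths[h.template_id],
                t_start=h.approx_t_interval[0],
                t_end=h.approx_t_interval[1],
                matches=h.ddf_score,
                columns=h.approx_t_interval[1] - h.approx_t_interval[0],
                mapq=255,
                tags={"cm": h.ddf_score},
            )
        )
    return records
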