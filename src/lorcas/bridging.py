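"""Contig bridging with raw reads.

Raw reads are mapped to contigs; a read hitting the ends of two different
contigs becomes a link candidate, classified as a gap read (positive gap
between the contig ends) or an overlapped read (the contig ends overlap).
Per contig pair and orientation class, candidates are clustered by gap
length (single linkage, 1 kb window) and the cluster with the largest
summed score (score = sum of identity x length over the read's two contig
hits) is chosen.  Chosen links form a bridge graph whose transitive edges
are removed; linear paths are emitted, splicing the representative read's
gap segment between contigs (or merging overlapped ends).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median
from typing import Optional, Sequence

from . import _align, candidates as cand_mod, correction
from .assembly import Contig
from .io_core import PipelineConfig, RawRead

logger = logging.getLogger("lorcas")


@dataclass
class ContigHit:
    read_id: str
    contig_id: str
    strand: str
    read_interval: tuple[int, int]
    contig_interval: tuple[int, int]  # forward contig coordinates
    identity: float
    length: int  # alignment columns

    def __post_init__(self):
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity outside [0,1]")

    @property
    def score(self) -> float:
        return self.identity * self.length


@dataclass
class LinkCandidate:
    read_id: str
    a_id: str  # first contig along the read
    b_id: str
    strand_a: str
    strand_b: str
    kind: str  # "gap" | "overlapped"
    gap_len: int  # negative = contig ends overlap
    score: float
    # junction interval on the read (start may exceed end when gap_len < 0)
    junction: tuple[int, int] = (0, 0)

    @property
    def orientation(self) -> str:
        return "same" if self.strand_a == self.strand_b else "different"

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.a_id, self.b_id)))


@dataclass
class LinkCluster:
    members: list[LinkCandidate]

    @property
    def total_score(self) -> float:
        return sum(m.score for m in self.members)

    @property
    def median_gap(self) -> float:
        return median(m.gap_len for m in self.members)

    @property
    def representative(self) -> LinkCandidate:
        return max(self.members, key=lambda m: (m.score, m.read_id))


@dataclass
class BridgeGraph:
    # oriented contig adjacency: (a_id, strand_a) -> (b_id, strand_b)
    edges: list[LinkCandidate] = field(default_factory=list)


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------


def map_raw_to_contigs(
    raw_reads: Sequence[RawRead],
    contigs: Sequence[Contig],
    config: PipelineConfig,
    min_hit_length: Optional[int] = None,
) -> list[ContigHit]:
    """Seed-and-chain each raw read against the contig set, refine with the
    sensitive aligner."""
    if min_hit_length is None:
        min_hit_length = config.bridge_min_hit_length
    ctg_reads = [RawRead(c.id, c.sequence) for c in contigs]
    index = cand_mod.index_kmers(
        ctg_reads, config.kmer_size, config.kmer_stride,
        max_occ=config.kmer_max_occ,
    )
    hits: list[ContigHit] = []
    margin = config.bridge_end_window + 1000
    for read in raw_reads:
        tcodes = _align.encode(read.sequence)
        cand_hits = cand_mod.find_candidates(
            read, index, config.ddf_epsilon, config.min_chain_anchors,
            exclude_self=False,
        )
        # only junction candidates matter: >= 2 contigs, hits near an end
        if len({ch.candidate_id for ch in cand_hits}) < 2:
            continue
        near_end = []
        for ch in cand_hits:
            clen = int(index.lengths[index.read_index(ch.candidate_id)])
            s, e = ch.approx_c_interval
            if s < margin or clen - e < margin:
                near_end.append(ch)
        if len({ch.candidate_id for ch in near_end}) < 2:
            continue
        cand_hits = near_end
        best_by_ctg: dict[tuple[str, str], ContigHit] = {}
        for ch in cand_hits:
            ci = index.read_index(ch.candidate_id)
            cori, _ = correction._orient_candidate(
                ctg_reads[ci], index.codes[ci], ch, config.kmer_size
            )
            res = correction.sensitive_align(tcodes, cori, max_difference=0.5)
            if res is None:
                continue
            ops, t_iv, c_iv = res
            if t_iv[1] - t_iv[0] < min_hit_length:
                continue
            c_fwd = correction._to_forward(c_iv, ctg_reads[ci].length, ch.strand)
            hit = ContigHit(
                read.id, ch.candidate_id, ch.strand, t_iv, c_fwd,
                _align.identity(ops), len(ops),
            )
            key = (read.id, ch.candidate_id)
            prev = best_by_ctg.get(key)
            if prev is None or hit.score > prev.score:
                best_by_ctg[key] = hit
        hits.extend(best_by_ctg[k] for k in sorted(best_by_ctg))
    return hits


# ---------------------------------------------------------------------------
# link classification
# ---------------------------------------------------------------------------


def _end_geometry(hit: ContigHit, contig_len: int, role: str, end_window: int):
    """Overhang of the contig past the read junction, or None if the hit is
    not an end hit.

    ``role`` 'first' means the read continues past this contig's trailing
    end; 'second' means the read arrived at this contig's leading end.
    """
    cs, ce = hit.contig_interval
    if (role == "first") == (hit.strand == "+"):
        # junction at the contig's right terminus
        tail = contig_len - ce
    else:
        tail = cs
    return tail if tail <= end_window else None


def classify_link(
    read: RawRead,
    hit_a: ContigHit,
    hit_b: ContigHit,
    contig_lengths: dict[str, int],
    end_window: int = 2000,
) -> Optional[LinkCandidate]:
    """Turn two end hits of one read into a gap/overlapped link candidate."""
    if hit_a.contig_id == hit_b.contig_id:
        return None
    # order the hits along the read
    if hit_a.read_interval[0] > hit_b.read_interval[0]:
        hit_a, hit_b = hit_b, hit_a
    tail_a = _end_geometry(hit_a, contig_lengths[hit_a.contig_id], "first", end_window)
    head_b = _end_geometry(hit_b, contig_lengths[hit_b.contig_id], "second", end_window)
    if tail_a is None or head_b is None:
        return None
    j_start = hit_a.read_interval[1] + tail_a
    j_end = hit_b.read_interval[0] - head_b
    gap = j_end - j_start
    return LinkCandidate(
        read_id=read.id,
        a_id=hit_a.contig_id,
        b_id=hit_b.contig_id,
        strand_a=hit_a.strand,
        strand_b=hit_b.strand,
        kind="gap" if gap >= 0 else "overlapped",
        gap_len=gap,
        score=hit_a.score + hit_b.score,
        junction=(j_start, j_end),
    )


def cluster_links(
    links: Sequence[LinkCandidate], window: int = 1000
) -> list[LinkCluster]:
    """Single-linkage clustering on sorted gap lengths."""
    if not links:
        return []
    ordered = sorted(links, key=lambda l: (l.gap_len, l.read_id))
    clusters: list[list[LinkCandidate]] = [[ordered[0]]]
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.gap_len - prev.gap_len < window:
            clusters[-1].append(cur)
        else:
            clusters.append([cur])
    return [LinkCluster(c) for c in clusters]


def choose_cluster(clusters: Sequence[LinkCluster]) -> Optional[LinkCluster]:
    """Largest total score; ties go to the smaller median |gap|."""
    if not clusters:
        return None
    return max(
        clusters,
        key=lambda c: (c.total_score, -abs(c.median_gap)),
    )


# ---------------------------------------------------------------------------
# bridge graph and emission
# ---------------------------------------------------------------------------


def _select_links(
    hits: Sequence[ContigHit],
    raw_by_id: dict[str, RawRead],
    contig_lengths: dict[str, int],
    config: PipelineConfig,
) -> list[LinkCandidate]:
    by_read: dict[str, list[ContigHit]] = {}
    for h in hits:
        by_read.setdefault(h.read_id, []).append(h)
    candidates: list[LinkCandidate] = []
    for rid in sorted(by_read):
        rhits = sorted(by_read[rid], key=lambda h: h.read_interval)
        for i in range(len(rhits)):
            for j in range(i + 1, len(rhits)):
                link = classify_link(
                    raw_by_id[rid], rhits[i], rhits[j], contig_lengths,
                    config.bridge_end_window,
                )
                if link is not None:
                    candidates.append(link)
    # one chosen link per contig pair + orientation class
    grouped: dict[tuple, list[LinkCandidate]] = {}
    for link in candidates:
        grouped.setdefault((link.pair, link.orientation), []).append(link)
    chosen: list[LinkCandidate] = []
    for key in sorted(grouped):
        clusters = cluster_links(grouped[key], config.bridge_cluster_window)
        best = choose_cluster(clusters)
        if best is not None:
            rep = best.representative
            rep = LinkCandidate(
                rep.read_id, rep.a_id, rep.b_id, rep.strand_a, rep.strand_b,
                rep.kind, rep.gap_len, best.total_score, rep.junction,
            )
            chosen.append(rep)
    return chosen


def _transitive_prune(links: list[LinkCandidate], contig_lengths, fuzz: int):
    """Drop a link implied by two shorter links through a middle contig."""
    adj: dict[tuple[str, str], dict[str, LinkCandidate]] = {}
    for l in links:
        adj.setdefault((l.a_id, l.b_id), {})[l.orientation] = l
    drop: set[int] = set()
    for i, l in enumerate(links):
        for j, m in enumerate(links):
            if m.a_id != l.a_id and m.b_id != l.a_id:
                continue
            for k, n in enumerate(links):
                if i in (j, k) or j == k:
                    continue
                # path a -(m)- w -(n)- b implying l: a - b
                ends_m = {m.a_id, m.b_id}
                ends_n = {n.a_id, n.b_id}
                shared = ends_m & ends_n
                if not shared:
                    continue
                (w,) = tuple(shared)[:1]
                if {l.a_id, l.b_id} != (ends_m | ends_n) - {w}:
                    continue
                implied = m.gap_len + contig_lengths[w] + n.gap_len
                if abs(l.gap_len - implied) <= fuzz:
                    drop.add(i)
    return [l for i, l in enumerate(links) if i not in drop]


def _enforce_end_uniqueness(links: list[LinkCandidate]) -> list[LinkCandidate]:
    """A contig end joined by more than one link is a branch: no merge."""

    def ends(l: LinkCandidate):
        ea = (l.a_id, "E" if l.strand_a == "+" else "B")
        eb = (l.b_id, "B" if l.strand_b == "+" else "E")
        return ea, eb

    count: dict[tuple[str, str], int] = {}
    for l in links:
        for e in ends(l):
            count[e] = count.get(e, 0) + 1
    return [l for l in links if all(count[e] == 1 for e in ends(l))]


def bridge_and_emit(
    contigs: Sequence[Contig],
    links: Sequence[LinkCandidate],
    raw_by_id: dict[str, RawRead],
    fuzz: int = 2000,
) -> list[Contig]:
    """Merge contig chains along chosen links; unlinked contigs pass through."""
    contig_lengths = {c.id: c.length for c in contigs}
    links = _transitive_prune(list(links), contig_lengths, fuzz)
    links = _enforce_end_uniqueness(links)

    # oriented adjacency: joining happens in the read frame, contig A oriented
    # by strand_a followed by contig B oriented by strand_b
    nxt: dict[tuple[str, str], LinkCandidate] = {}
    prv: dict[tuple[str, str], LinkCandidate] = {}
    for l in links:
        nxt[(l.a_id, l.strand_a)] = l
        prv[(l.b_id, l.strand_b)] = l
        # the same physical join read in the other direction
        nxt[(l.b_id, _flip(l.strand_b))] = l
        prv[(l.a_id, _flip(l.strand_a))] = l

    by_id = {c.id: c for c in contigs}
    used: set[str] = set()
    out: list[Contig] = []
    idx = 0

    def oriented(cid: str, strand: str) -> str:
        s = by_id[cid].sequence
        return s if strand == "+" else _align.revcomp(s)

    def chain_start(cid: str, strand: str):
        """Walk backwards to the start of this contig's chain."""
        node = (cid, strand)
        seen = {node}
        while node in prv:
            l = prv[node]
            if node == (l.b_id, l.strand_b):
                node = (l.a_id, l.strand_a)
            else:
                node = (l.b_id, _flip(l.strand_b))
            if node in seen:  # cycle: break at the lowest-score edge
                logger.warning("bridge: cycle detected at %s, breaking", node)
                break
            seen.add(node)
        return node

    for cid in sorted(by_id):
        if cid in used:
            continue
        node = chain_start(cid, "+")
        if node[0] in used:
            continue
        parts = [oriented(*node)]
        layout = [(node[0], node[1], 0)]
        used.add(node[0])
        while node in nxt:
            l = nxt[node]
            forwardly = node == (l.a_id, l.strand_a)
            if forwardly:
                nxt_node = (l.b_id, l.strand_b)
                j_start, j_end = l.junction
                gap_seq = raw_by_id[l.read_id].sequence[j_start:j_end]
            else:
                nxt_node = (l.a_id, _flip(l.strand_a))
                j_start, j_end = l.junction
                gap_seq = _align.revcomp(
                    raw_by_id[l.read_id].sequence[j_start:j_end]
                )
            if nxt_node[0] in used:
                break
            nseq = oriented(*nxt_node)
            if l.gap_len >= 0:
                parts.append(gap_seq)
                parts.append(nseq)
            else:
                parts.append(nseq[-l.gap_len :])
            used.add(nxt_node[0])
            layout.append((nxt_node[0], nxt_node[1], sum(len(p) for p in parts[:-1])))
            node = nxt_node
        out.append(Contig(f"scaf{idx:04d}", "".join(parts), layout))
        idx += 1
    return out


def _flip(s: str) -> str:
    return "-" if s == "+" else "+"


def bridge_stage(
    contigs: Sequence[Contig],
    raw_reads: Sequence[RawRead],
    config: PipelineConfig,
) -> tuple[list[Contig], list[LinkCandidate]]:
    hits = map_raw_to_contigs(raw_reads, contigs, config)
    raw_by_id = {r.id: r for r in raw_reads}
    contig_lengths = {c.id: c.length for c in contigs}
    links = _select_links(hits, raw_by_id, contig_lengths, config)
    merged = bridge_and_emit(
        contigs, links, raw_by_id, fuzz=2 * config.bridge_cluster_window
    )
    return merged, links
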