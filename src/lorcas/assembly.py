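"""Overlap filtering, string-graph construction, and contig extraction.

Overlaps are filtered by per-read coverage statistics and by adaptive
identity/overhang thresholds (global floor plus a per-read local cutoff).
Proper dovetail overlaps then build a directed string graph over oriented
read ends (Myers-style: contained reads removed, each dovetail yields an
edge and its dual).  The graph is simplified by transitive reduction,
best-in/best-out edge marking, and tip/bubble/spurious-link removal before
maximal linear paths are spliced into contigs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _align
from .io_core import PafRecord, RawRead

logger = logging.getLogger("lorcas")

Node = tuple[str, str]  # (read id, orientation '+'/'-')


@dataclass
class OverlapRecord:
    """A pairwise overlap; all intervals on each read's forward strand."""

    a_id: str
    b_id: str
    strand: str  # orientation of b relative to a
    a_interval: tuple[int, int]
    b_interval: tuple[int, int]
    a_len: int
    b_len: int
    identity: float
    length: int  # alignment columns

    def __post_init__(self):
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity outside [0,1]")
        for iv, ln in ((self.a_interval, self.a_len), (self.b_interval, self.b_len)):
            if not (0 <= iv[0] < iv[1] <= ln):
                raise ValueError(f"interval {iv} outside read of length {ln}")

    def b_oriented(self) -> tuple[int, int]:
        """b interval in the frame aligned to a's forward strand."""
        if self.strand == "+":
            return self.b_interval
        return self.b_len - self.b_interval[1], self.b_len - self.b_interval[0]

    def overhangs(self) -> tuple[int, int, int, int]:
        """(a_left, a_right, b_left, b_right) in the oriented frame."""
        bs, be = self.b_oriented()
        return (
            self.a_interval[0],
            self.a_len - self.a_interval[1],
            bs,
            self.b_len - be,
        )

    def overhang(self) -> int:
        """Unaligned inner overhang (miniasm-style)."""
        al, ar, bl, br = self.overhangs()
        return min(al, bl) + min(ar, br)

    def interval_of(self, read_id: str) -> tuple[int, int]:
        if read_id == self.a_id:
            return self.a_interval
        if read_id == self.b_id:
            return self.b_interval
        raise KeyError(read_id)

    def to_paf(self) -> PafRecord:
        matches = int(round(self.identity * self.length))
        return PafRecord(
            self.a_id, self.a_len, self.a_interval[0], self.a_interval[1],
            self.strand, self.b_id, self.b_len, self.b_interval[0],
            self.b_interval[1], matches, self.length, 255,
            {"df": 1.0 - self.identity},
        )


@dataclass
class CoverageStats:
    read_id: str
    c_min: int
    c_max: int

    @property
    def c_diff(self) -> int:
        return self.c_max - self.c_min


@dataclass
class Edge:
    ext_len: int  # bases the target appends to a path
    ovl_len: int  # overlap span, ranks best-in/best-out
    reduced: bool = False


@dataclass
class Contig:
    id: str
    sequence: str
    layout: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)


def _flip(o: str) -> str:
    return "-" if o == "+" else "+"


def dual(u: Node, v: Node) -> tuple[Node, Node]:
    return (v[0], _flip(v[1])), (u[0], _flip(u[1]))


class StringGraph:
    """Directed graph over oriented reads with dual-edge symmetry."""

    def __init__(self, reads: Optional[dict[str, str]] = None):
        self.reads: dict[str, str] = reads or {}
        self.out: dict[Node, dict[Node, Edge]] = {}
        self.inn: dict[Node, dict[Node, Edge]] = {}

    # -- construction ------------------------------------------------------
    def add_node(self, node: Node) -> None:
        self.out.setdefault(node, {})
        self.inn.setdefault(node, {})

    def add_edge(self, u: Node, v: Node, ext_len: int, ovl_len: int,
                 dual_ext_len: Optional[int] = None,
                 with_dual: bool = True) -> None:
        """Insert u->v and its dual.  ``ext_len`` is the sequence v appends
        to a path through u; the dual edge appends from u's other end, so it
        carries its own extension length (defaults to ``ext_len``)."""
        if u[0] == v[0]:
            return  # no self-loops
        self.add_node(u)
        self.add_node(v)
        e = Edge(ext_len, ovl_len)
        self.out[u][v] = e
        self.inn[v][u] = e
        if with_dual:
            du, dv = dual(u, v)
            if dv not in self.out.get(du, {}):
                self.add_edge(
                    du, dv,
                    ext_len if dual_ext_len is None else dual_ext_len,
                    ovl_len, with_dual=False,
                )

    def remove_edge(self, u: Node, v: Node, with_dual: bool = True) -> None:
        self.out.get(u, {}).pop(v, None)
        self.inn.get(v, {}).pop(u, None)
        if with_dual:
            du, dv = dual(u, v)
            self.remove_edge(du, dv, with_dual=False)

    def remove_node(self, node: Node, with_dual: bool = True) -> None:
        for v in list(self.out.get(node, {})):
            self.remove_edge(node, v, with_dual=True)
        for u in list(self.inn.get(node, {})):
            self.remove_edge(u, node, with_dual=True)
        self.out.pop(node, None)
        self.inn.pop(node, None)
        if with_dual:
            self.remove_node((node[0], _flip(node[1])), with_dual=False)

    # -- queries -----------------------------------------------------------
    def nodes(self) -> list[Node]:
        return list(self.out)

    def edges(self) -> list[tuple[Node, Node, Edge]]:
        return [(u, v, e) for u, nbrs in self.out.items() for v, e in nbrs.items()]

    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self.out.values())

    def oriented_seq(self, node: Node) -> str:
        seq = self.reads[node[0]]
        return seq if node[1] == "+" else _align.revcomp(seq)

    def copy(self) -> "StringGraph":
        g = StringGraph(dict(self.reads))
        for u, v, e in self.edges():
            g.add_node(u)
            g.add_node(v)
            g.out[u][v] = Edge(e.ext_len, e.ovl_len, e.reduced)
            g.inn[v][u] = g.out[u][v]
        return g

    def to_gfa(self, path) -> None:
        from .io_core import write_gfa

        segs = {rid: (seq if seq else 0) for rid, seq in self.reads.items()
                if (rid, "+") in self.out or (rid, "-") in self.out}
        links = [
            (u[0], u[1], v[0], v[1], e.ovl_len) for u, v, e in self.edges()
        ]
        write_gfa(segs, links, path)


# ---------------------------------------------------------------------------
# overlap filters
# ---------------------------------------------------------------------------


def coverage_stats(
    read_id: str, read_len: int, overlaps: Sequence[OverlapRecord],
    end_clip: int = 0,
) -> CoverageStats:
    cov = np.zeros(read_len + 1, np.int32)
    for ov in overlaps:
        s, e = ov.interval_of(read_id)
        cov[s] += 1
        cov[e] -= 1
    per_base = np.cumsum(cov[:-1])
    if end_clip and read_len > 2 * end_clip:
        per_base = per_base[end_clip : read_len - end_clip]
    return CoverageStats(read_id, int(per_base.min()), int(per_base.max()))


def coverage_filter(
    reads: Sequence[RawRead],
    overlaps: Sequence[OverlapRecord],
    min_coverage: int = 2,
    max_coverage: int = 200,
    max_diff_coverage: int = 150,
    end_clip: int = 500,
):
    """Remove reads with anomalous per-base overlap coverage (and their
    overlaps).  Coverage extremes are taken on the read interior (ends
    clipped) so terminal reads of a linear layout are not penalized."""
    by_read: dict[str, list[OverlapRecord]] = {r.id: [] for r in reads}
    for ov in overlaps:
        if ov.a_id in by_read:
            by_read[ov.a_id].append(ov)
        if ov.b_id in by_read:
            by_read[ov.b_id].append(ov)
    bad: set[str] = set()
    for r in reads:
        st = coverage_stats(r.id, r.length, by_read[r.id], end_clip)
        if (
            st.c_min < min_coverage
            or st.c_max > max_coverage
            or st.c_diff > max_diff_coverage
        ):
            bad.add(r.id)
    kept_reads = [r for r in reads if r.id not in bad]
    kept_ovl = [o for o in overlaps if o.a_id not in bad and o.b_id not in bad]
    if bad:
        logger.info("coverage_filter: removed %d reads", len(bad))
    return kept_reads, kept_ovl


def adaptive_overlap_filter(
    overlaps: Sequence[OverlapRecord],
    global_identity: float = 0.90,
    global_overhang: int = 500,
    alpha: float = 2.0,
    sd_floor: float = 0.01,
    overhang_sd_floor: float = 50.0,
) -> list[OverlapRecord]:
    """Global floor plus per-read local cutoffs on identity and overhang.

    Local identity cutoff of a read = mean(identities of its overlaps) -
    alpha*sd; the effective cutoff is max(global, local) and must hold for
    both reads.  The local overhang bound = mean + alpha*sd of the read's
    overlap overhangs, combined as min(global, local).  The sd is floored
    so a read whose overlaps are uniformly excellent does not reject its
    own (still excellent) neighbours.
    """
    ids: dict[str, list[float]] = {}
    ohs: dict[str, list[int]] = {}
    for ov in overlaps:
        for rid in (ov.a_id, ov.b_id):
            ids.setdefault(rid, []).append(ov.identity)
            ohs.setdefault(rid, []).append(ov.overhang())

    def local_identity(rid: str) -> float:
        v = np.asarray(ids[rid])
        if len(v) < 2:
            return global_identity
        return float(v.mean() - alpha * max(v.std(), sd_floor))

    def local_overhang(rid: str) -> float:
        v = np.asarray(ohs[rid], dtype=float)
        if len(v) < 2:
            return float(global_overhang)
        return float(v.mean() + alpha * max(v.std(), overhang_sd_floor))

    id_cut = {rid: max(global_identity, local_identity(rid)) for rid in ids}
    oh_cut = {rid: min(float(global_overhang), local_overhang(rid)) for rid in ohs}
    kept = []
    for ov in overlaps:
        cut = max(id_cut[ov.a_id], id_cut[ov.b_id])
        bound = min(oh_cut[ov.a_id], oh_cut[ov.b_id])
        if ov.identity >= cut and ov.overhang() <= min(global_overhang, bound):
            kept.append(ov)
    return kept


# ---------------------------------------------------------------------------
# string graph
# ---------------------------------------------------------------------------


def build_string_graph(
    reads: Sequence[RawRead],
    overlaps: Sequence[OverlapRecord],
    overhang_eps: int = 200,
    min_overlap: int = 500,
    keep_isolated: bool = True,
) -> StringGraph:
    """Myers-style construction: contained reads out, dovetails become dual
    extension edges.  ``keep_isolated=False`` drops reads that end up with
    no graph edges (chaff whose overlaps were all filtered)."""
    lengths = {r.id: r.length for r in reads}
    contained: set[str] = set()
    for ov in overlaps:
        al, ar, bl, br = ov.overhangs()
        if bl <= overhang_eps and br <= overhang_eps:
            if not (al <= overhang_eps and ar <= overhang_eps):
                contained.add(ov.b_id)
            else:
                # mutual containment: drop the shorter (tie -> larger id)
                pair = sorted(
                    (ov.a_id, ov.b_id), key=lambda i: (lengths[i], i)
                )
                contained.add(pair[0])
        elif al <= overhang_eps and ar <= overhang_eps:
            contained.add(ov.a_id)

    g = StringGraph({r.id: r.sequence for r in reads if r.id not in contained})
    for r in reads:
        if r.id not in contained:
            g.add_node((r.id, "+"))
            g.add_node((r.id, "-"))
    for ov in overlaps:
        if ov.a_id in contained or ov.b_id in contained:
            continue
        span = ov.a_interval[1] - ov.a_interval[0]
        if span < min_overlap:
            continue
        al, ar, bl, br = ov.overhangs()
        bo = ov.strand
        if ar <= overhang_eps and bl <= overhang_eps and al > bl:
            # a suffix overlaps b prefix: path a -> b; the dual path walks
            # b' -> a' and appends a's left overhang instead
            bs, be = ov.b_oriented()
            g.add_edge((ov.a_id, "+"), (ov.b_id, bo),
                       ext_len=ov.b_len - be, ovl_len=span,
                       dual_ext_len=ov.a_interval[0])
        elif al <= overhang_eps and br <= overhang_eps and ar > br:
            # b suffix overlaps a prefix: path b -> a
            bs, be = ov.b_oriented()
            g.add_edge((ov.b_id, bo), (ov.a_id, "+"),
                       ext_len=lengths[ov.a_id] - ov.a_interval[1], ovl_len=span,
                       dual_ext_len=bs)
        # anything else is an internal match: ignored
    if not keep_isolated:
        for rid in list(g.reads):
            if not g.out.get((rid, "+")) and not g.inn.get((rid, "+")) \
                    and not g.out.get((rid, "-")) and not g.inn.get((rid, "-")):
                g.remove_node((rid, "+"))
                g.remove_node((rid, "-"))
                del g.reads[rid]
    return g


def transitive_reduction(g: StringGraph, fuzz: int = 500) -> StringGraph:
    """Remove edges implied by a two-edge path of compatible length."""
    to_remove: list[tuple[Node, Node]] = []
    for v in g.nodes():
        nbrs = g.out[v]
        if len(nbrs) < 2:
            continue
        targets = set(nbrs)
        for w, e_vw in nbrs.items():
            for x, e_wx in g.out.get(w, {}).items():
                if x in targets and x != w:
                    if abs(nbrs[x].ext_len - (e_vw.ext_len + e_wx.ext_len)) <= fuzz:
                        to_remove.append((v, x))
    for u, v in to_remove:
        if v in g.out.get(u, {}):
            g.out[u][v].reduced = True
    for u, v in to_remove:
        g.remove_edge(u, v)
    return g


def best_edge_prune(g: StringGraph) -> StringGraph:
    """Keep only edges marked best-out or best-in by overlap length."""
    marked: set[tuple[Node, Node]] = set()
    for v in g.nodes():
        outs = g.out.get(v, {})
        if outs:
            best = max(outs.items(), key=lambda kv: (kv[1].ovl_len, kv[0]))[0]
            marked.add((v, best))
        inns = g.inn.get(v, {})
        if inns:
            best = max(inns.items(), key=lambda kv: (kv[1].ovl_len, kv[0]))[0]
            marked.add((best, v))
    for u, v, _ in list(g.edges()):
        if (u, v) not in marked and dual(u, v) not in marked:
            g.remove_edge(u, v)
    return g


def _linear_walk(g: StringGraph, start: Node, limit: int) -> list[Node]:
    path = [start]
    node = start
    while len(path) <= limit:
        outs = list(g.out.get(node, {}))
        if len(outs) != 1:
            break
        nxt = outs[0]
        if len(g.inn.get(nxt, {})) != 1 or nxt in path:
            break
        path.append(nxt)
        node = nxt
    return path


def clean_graph(g: StringGraph, tip_len: int = 3, bubble_depth: int = 5,
                spurious_fraction: float = 0.25) -> StringGraph:
    """Remove tips, simple bubbles, and weakly supported (spurious) links."""
    # tips: short chains that start at a dead end and attach to a junction
    def _tip_chain(v):
        """(chain, attaching edge strength) or None if v is not a tip."""
        if v not in g.out or g.inn.get(v):
            return None
        chain = [v]
        node = v
        while len(g.out.get(node, {})) == 1 and len(chain) <= tip_len:
            nxt = next(iter(g.out[node]))
            if len(g.inn.get(nxt, {})) > 1:
                if len(chain) <= tip_len:
                    return chain, g.out[node][nxt].ovl_len
                return None
            chain.append(nxt)
            node = nxt
        return None

    changed = True
    while changed:
        changed = False
        found = []
        for v in list(g.nodes()):
            tip = _tip_chain(v)
            if tip is not None:
                found.append((tip[1], tip[0]))
        # weakest-supported tips go first; re-verify before each removal so
        # a junction that loses one spur keeps its (now unambiguous) other arm
        for _, chain in sorted(found, key=lambda x: (x[0], x[1])):
            if _tip_chain(chain[0]) is not None:
                for n in chain:
                    g.remove_node(n)
                changed = True
    # bubbles: two short parallel linear branches that reconverge
    for v in list(g.nodes()):
        outs = list(g.out.get(v, {}))
        if len(outs) != 2:
            continue
        branches = []
        for b in outs:
            path = _linear_walk(g, b, bubble_depth)
            end_next = list(g.out.get(path[-1], {}))
            branches.append((path, end_next))
        (p1, n1), (p2, n2) = branches
        if len(n1) == 1 and len(n2) == 1 and n1[0] == n2[0] and not set(p1) & set(p2):
            s1 = sum(g.out[a][b].ovl_len for a, b in zip([v] + p1, p1 + n1))
            s2 = sum(g.out[a][b].ovl_len for a, b in zip([v] + p2, p2 + n2))
            drop = p2 if (s1, p2[0]) >= (s2, p1[0]) else p1
            for node in drop:
                g.remove_node(node)
    # spurious links: much weaker than the node's best edge on both sides
    for u, v, e in list(g.edges()):
        outs = g.out.get(u)
        inns = g.inn.get(v)
        if not outs or not inns or v not in outs:
            continue
        best_u = max(x.ovl_len for x in outs.values())
        best_v = max(x.ovl_len for x in inns.values())
        if (
            len(outs) > 1
            and len(inns) > 1
            and e.ovl_len < spurious_fraction * min(best_u, best_v)
        ):
            g.remove_edge(u, v)
    return g


def extract_contigs(g: StringGraph, prefix: str = "ctg") -> list[Contig]:
    """Splice maximal linear paths into contigs (branches break paths)."""
    visited: set[Node] = set()
    contigs: list[Contig] = []

    def is_start(v: Node) -> bool:
        inn = g.inn.get(v, {})
        if len(inn) != 1:
            return True
        (pred,) = inn
        return len(g.out.get(pred, {})) != 1

    starts = sorted((v for v in g.nodes() if is_start(v)))
    idx = 0

    def emit(path: list[Node]) -> None:
        nonlocal idx
        seq_parts = [g.oriented_seq(path[0])]
        layout = [(path[0][0], path[0][1], 0)]
        offset = len(seq_parts[0])
        for a, b in zip(path, path[1:]):
            e = g.out[a][b]
            bseq = g.oriented_seq(b)
            ext = bseq[len(bseq) - e.ext_len :] if e.ext_len else ""
            layout.append((b[0], b[1], offset - (len(bseq) - e.ext_len)))
            seq_parts.append(ext)
            offset += len(ext)
        contigs.append(Contig(f"{prefix}{idx:04d}", "".join(seq_parts), layout))
        idx += 1
        for node in path:
            visited.add(node)
            visited.add((node[0], _flip(node[1])))

    for start in starts:
        if start in visited:
            continue
        path = [start]
        node = start
        while True:
            outs = list(g.out.get(node, {}))
            if len(outs) != 1:
                break
            nxt = outs[0]
            if len(g.inn.get(nxt, {})) != 1 or nxt in visited or nxt in path:
                break
            path.append(nxt)
            node = nxt
        emit(path)
    # remaining nodes belong to cycles: break at the smallest node
    for v in sorted(g.nodes()):
        if v in visited:
            continue
        path = [v]
        node = v
        while True:
            outs = [x for x in g.out.get(node, {}) if x not in path]
            if not outs:
                break
            nxt = sorted(outs)[0]
            if nxt in visited:
                break
            path.append(nxt)
            node = nxt
        emit(path)
    return contigs


def dedupe_contigs(
    contigs: list[Contig],
    min_contained_fraction: float = 0.85,
) -> list[Contig]:
    """Drop contigs whose sequence is (almost) fully contained in a longer
    contig -- redundant parallel paths from residual low-quality reads."""
    from . import metrics as met  # local import: metrics depends on others

    ordered = sorted(contigs, key=lambda c: -c.length)
    kept: list[Contig] = []
    for c in ordered:
        dup = False
        q = _align.encode(c.sequence)
        for big in kept:
            if big.length < c.length:
                continue
            ref = _align.encode(big.sequence)
            for variant in (q, _align.revcomp_codes(q)):
                ops, _, _ = met.align_to_reference(variant, ref)
                m = _align.ops_counts(ops)[0]
                if m / c.length >= min_contained_fraction:
                    dup = True
                    break
            if dup:
                break
        if dup:
            logger.info("dedupe: dropped contained contig %s (%d bp)", c.id, c.length)
        else:
            kept.append(c)
    return sorted(kept, key=lambda c: c.id)


def assemble(
    reads: Sequence[RawRead],
    overlaps: Sequence[OverlapRecord],
    config,
    gfa_dir=None,
) -> tuple[list[Contig], StringGraph]:
    """Filter overlaps, build/clean the graph, extract contigs."""
    reads2, ovl2 = coverage_filter(
        reads, overlaps, config.min_coverage, config.max_coverage,
        config.max_diff_coverage,
    )
    ovl3 = adaptive_overlap_filter(
        ovl2, config.overlap_global_identity, config.overlap_global_overhang,
        config.overlap_alpha,
    )
    g = build_string_graph(reads2, ovl3, min_overlap=config.min_overlap_length,
                           keep_isolated=False)
    if gfa_dir is not None:
        g.to_gfa(f"{gfa_dir}/string_graph.raw.gfa")
    transitive_reduction(g, config.transitive_fuzz)
    best_edge_prune(g)
    clean_graph(g, config.tip_length, config.bubble_depth, config.spurious_fraction)
    if gfa_dir is not None:
        g.to_gfa(f"{gfa_dir}/string_graph.clean.gfa")
    contigs = dedupe_contigs(extract_contigs(g))
    return contigs, g
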